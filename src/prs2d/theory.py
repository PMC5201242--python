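"""Analytic predictive performance of 1D/2D PRS under independent SNPs.

Model: standardized outcome Y = sum_t beta_t g_t + eps with standardized
independent genotypes, M1 causal and M3 null SNPs in the high-prior set,
M2 causal and M4 null SNPs in the low-prior set.  A discovery GWAS of size N
yields beta_hat ~ N(beta, 1/N) per SNP (marginal-regression asymptotics with
Var(Y) = Var(g) = 1 and small per-SNP effects).  The expected predictive
correlation of the threshold-selected score is

    E(PCC) ~ [ M1 J1(a1) + M2 J1(a2) ]
             / sqrt( M1 J2(a1) + M2 J2(a2) + M3 a1 v(0) + M4 a2 v(0) )

where J1(a) = Int beta * e(beta) * pow(beta) f(beta) dbeta,
J2(a) = Int v(beta) * pow(beta) f(beta) dbeta, e and v are the first and
second moments of beta_hat conditional on selection, pow is two-sided power,
and f is the causal effect-size distribution (a two-component normal mixture,
shared by both sets).  Integrals use Gauss-Hermite quadrature per component.

For a binary trait a liability-threshold construction maps PCC to AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .shrinkage import threshold_lambda

__all__ = [
    "ArchitectureSpec",
    "TheoryResult",
    "detection_power",
    "truncated_moments",
    "expected_pcc",
    "optimal_theory_thresholds",
    "pcc_to_auc",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic-architecture parameters for theory and direct simulation.

    m1/m2 are causal SNP counts in the HP/LP sets, m3/m4 the null counts.
    sigma1_sq and sigma2_sq are the mixture component variances, scaled so the
    causal SNPs explain h1_sq + h2_sq of the unit trait variance:
    h1_sq = (m1+m2)*pi*sigma1_sq, h2_sq = (m1+m2)*(1-pi)*sigma2_sq.
    """

    m_total: int
    m1: int
    m2: int
    m3: int
    m4: int
    pi: float
    sigma1_sq: float
    sigma2_sq: float
    h1_sq: float
    h2_sq: float
    n_discovery: int
    prevalence: float | None = None
    delta: float | None = None

    def __post_init__(self) -> None:
        if self.m1 + self.m2 + self.m3 + self.m4 != self.m_total:
            raise ValueError("m1 + m2 + m3 + m4 must equal m_total")
        if not 0 < self.pi < 1:
            raise ValueError("pi must lie in (0, 1)")
        if self.h1_sq + self.h2_sq >= 1:
            raise ValueError("h1_sq + h2_sq must be < 1")
        n_causal = self.m1 + self.m2
        for name, h, comp in (
            ("h1_sq", self.h1_sq, n_causal * self.pi * self.sigma1_sq),
            ("h2_sq", self.h2_sq, n_causal * (1 - self.pi) * self.sigma2_sq),
        ):
            if abs(h - comp) > 1e-8 * max(1.0, h):
                raise ValueError(f"{name}={h} inconsistent with mixture scaling {comp}")

    @property
    def n_causal(self) -> int:
        return self.m1 + self.m2

    @property
    def hp_size(self) -> int:
        return self.m1 + self.m3

    @property
    def se(self) -> float:
        """Sampling SD of a marginal effect estimate, 1/sqrt(N)."""
        return 1.0 / np.sqrt(self.n_discovery)

    @property
    def enrichment(self) -> float:
        """Realized fold enrichment of causal SNPs in the HP set."""
        return (self.m1 / self.n_causal) / (self.hp_size / self.m_total)

    @classmethod
    def from_enrichment(
        cls,
        m_total: int,
        n_causal: int,
        hp_size: int,
        delta: float,
        n_discovery: int,
        pi: float = 0.1,
        h1_sq: float = 0.1,
        h2_sq: float = 0.4,
        prevalence: float | None = None,
    ) -> "ArchitectureSpec":
        """Build a spec from total counts and the HP enrichment fold Delta.

        The HP causal count is m1 = round(delta * n_causal * hp_size / m_total)
        (the expected overlap of a random HP set times delta).
        """
        m1 = int(round(delta * n_causal * hp_size / m_total))
        if m1 > min(n_causal, hp_size):
            raise ValueError(f"delta={delta} infeasible: overlap {m1} exceeds set sizes")
        m2 = n_causal - m1
        m3 = hp_size - m1
        m4 = m_total - n_causal - m3
        if min(m2, m3, m4) < 0:
            raise ValueError("infeasible architecture counts")
        return cls(
            m_total=m_total,
            m1=m1,
            m2=m2,
            m3=m3,
            m4=m4,
            pi=pi,
            sigma1_sq=h1_sq / (n_causal * pi),
            sigma2_sq=h2_sq / (n_causal * (1 - pi)),
            h1_sq=h1_sq,
            h2_sq=h2_sq,
            n_discovery=n_discovery,
            prevalence=prevalence,
            delta=delta,
        )


@dataclass(frozen=True)
class TheoryResult:
    e_pcc: float
    alpha1: float
    alpha2: float
    auc: float | None = None


def detection_power(n: int, beta, alpha) -> np.ndarray | float:
    """Two-sided power to detect effect beta at level alpha with N samples.

    Z = beta_hat/se ~ N(beta*sqrt(N), 1), so power = Phi(beta*sqrt(N) - z_{a/2})
    + Phi(-beta*sqrt(N) - z_{a/2}).  Equals alpha at beta = 0.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any((alpha <= 0) | (alpha > 1)) or n < 1:
        raise ValueError("need alpha in (0,1] and n >= 1")
    mu = np.asarray(beta, dtype=float) * np.sqrt(n)
    za = stats.norm.isf(alpha / 2.0)
    out = special.ndtr(mu - za) + special.ndtr(-mu - za)
    return out if out.ndim else float(out)


def _selection_pieces(beta, se, alpha):
    """(Q, E1, E2): selection probability and E[X 1_sel], E[X^2 1_sel].

    X ~ N(beta, se^2), selection is |X| > lambda(alpha).  Written in terms of
    standard-normal tail quantities of a = (lam-beta)/se (upper tail) and
    b = (-lam-beta)/se (lower tail); exact closed forms, stable in far tails
    because ratios are taken against logs downstream.
    """
    beta = np.asarray(beta, dtype=float)
    lam = threshold_lambda(alpha, 1.0) * se
    a = (lam - beta) / se
    b = (-lam - beta) / se
    phi_a, phi_b = stats.norm.pdf(a), stats.norm.pdf(b)
    q_hi, q_lo = special.ndtr(-a), special.ndtr(b)
    q = q_hi + q_lo
    ez1 = phi_a - phi_b  # E[Z 1_sel] for the standardized variable
    ez2 = q_hi + a * phi_a + q_lo - b * phi_b  # E[Z^2 1_sel]
    e1 = beta * q + se * ez1
    e2 = beta**2 * q + 2.0 * beta * se * ez1 + se**2 * ez2
    return q, e1, e2


def truncated_moments(beta, se, alpha):
    """(e, v): conditional moments E[X | sel], E[X^2 | sel] of the estimate.

    X ~ N(beta, se^2) conditioned on |X| > lambda(alpha).  When the selection
    probability underflows, the limits e -> sign tail mean and v are computed
    from the dominating tail via Mills ratios (stable for lambda/se up to ~40).
    """
    q, e1, e2 = _selection_pieces(beta, se, alpha)
    q = np.asarray(q, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(q > 0, e1 / np.where(q > 0, q, 1.0), np.nan)
        v = np.where(q > 0, e2 / np.where(q > 0, q, 1.0), np.nan)
    if np.any(q == 0):
        # deep-tail fallback on the log scale: dominant tail only
        beta_arr = np.broadcast_to(np.asarray(beta, dtype=float), q.shape)
        lam = threshold_lambda(alpha, 1.0) * se
        sign = np.where(beta_arr >= 0, 1.0, -1.0)
        a = (lam - sign * beta_arr) / se  # distance to the near threshold
        # Mills: E[X|X>lam] ~ beta + se*(a + 1/a) for a large
        mills = a + 1.0 / np.maximum(a, 1.0)
        e_deep = sign * (np.abs(beta_arr) + se * mills)
        e = np.where(q == 0, e_deep, e)
        v = np.where(q == 0, e_deep**2 + se**2, v)
    e = e if e.ndim else float(e)
    v = v if np.ndim(v) else float(v)
    return e, v


def _gauss_hermite_nodes(sigma_sq: float, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights so that sum w_i h(x_i) ~ Int h(b) N(0, sigma_sq) db."""
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
    return x * np.sqrt(sigma_sq), w / w.sum()  # weights sum to sqrt(2*pi)


def _mixture_integrals(arch: ArchitectureSpec, alpha: float, n_nodes: int):
    """(J1, J2) = (Int beta e pow f, Int v pow f) over the causal mixture."""
    se = arch.se
    j1 = 0.0
    j2 = 0.0
    for weight, s2 in ((arch.pi, arch.sigma1_sq), (1.0 - arch.pi, arch.sigma2_sq)):
        if s2 == 0:
            q, e1, e2 = _selection_pieces(0.0, se, alpha)
            j1 += weight * 0.0
            j2 += weight * e2
            continue
        nodes, wts = _gauss_hermite_nodes(s2, n_nodes)
        q, e1, e2 = _selection_pieces(nodes, se, alpha)
        # beta * e(beta) * pow = beta * E[X 1_sel]; v * pow = E[X^2 1_sel]
        j1 += weight * float(np.sum(wts * nodes * e1))
        j2 += weight * float(np.sum(wts * e2))
    return j1, j2


def expected_pcc(
    arch: ArchitectureSpec, alpha1: float, alpha2: float, *, n_nodes: int = 128
) -> float:
    """Expected predictive correlation of the 2D PRS at thresholds (a1, a2).

    alpha1 applies to the HP set (m1 causal + m3 null), alpha2 to the LP set.
    Returns 0 when nothing is expected to pass selection.  alpha1 == alpha2
    reduces to the 1D formula with a pooled threshold.
    """
    for a in (alpha1, alpha2):
        if not 0 < a <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    j1_hp, j2_hp = _mixture_integrals(arch, alpha1, n_nodes)
    j1_lp, j2_lp = _mixture_integrals(arch, alpha2, n_nodes)
    se = arch.se
    _, v0_hp = truncated_moments(0.0, se, alpha1)
    _, v0_lp = truncated_moments(0.0, se, alpha2)
    num = arch.m1 * j1_hp + arch.m2 * j1_lp
    den_sq = (
        arch.m1 * j2_hp
        + arch.m2 * j2_lp
        + arch.m3 * alpha1 * v0_hp
        + arch.m4 * alpha2 * v0_lp
    )
    if den_sq <= 0 or not np.isfinite(den_sq):
        return 0.0
    return float(num / np.sqrt(den_sq))


def optimal_theory_thresholds(
    arch: ArchitectureSpec, grid: Sequence[float], *, two_d: bool = True
) -> TheoryResult:
    """Grid-search maximizer of expected_pcc over thresholds.

    2D searches the Cartesian product of ``grid`` with itself; 1D constrains
    alpha1 == alpha2.  Deterministic; ties broken toward the earlier grid
    entry (stable argmax).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty threshold grid")
    best = (-np.inf, grid[0], grid[0])
    for a1 in grid:
        for a2 in grid if two_d else [a1]:
            val = expected_pcc(arch, a1, a2)
            if val > best[0]:
                best = (val, a1, a2)
    auc = (
        pcc_to_auc(best[0], arch.prevalence)
        if arch.prevalence is not None and 0 <= best[0] < 1
        else None
    )
    return TheoryResult(e_pcc=best[0], alpha1=best[1], alpha2=best[2], auc=auc)


def pcc_to_auc(pcc: float, prevalence: float, *, n_grid: int = 4001) -> float:
    """AUC of a score with predictive correlation ``pcc`` under liability threshold.

    Liability L = s + e with s ~ N(0, pcc^2) the score contribution and
    e ~ N(0, 1 - pcc^2); disease iff L > Phi^{-1}(1 - prevalence).  AUC is
    P(s_case > s_control), computed by deterministic numeric integration of
    the case density against the control CDF.  pcc = 0 gives 0.5.
    """
    if not 0 <= pcc < 1:
        raise ValueError("pcc must lie in [0, 1)")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if pcc == 0:
        return 0.5
    thr = stats.norm.isf(prevalence)
    sd_e = np.sqrt(1.0 - pcc**2)
    s = np.linspace(-8.0 * pcc, 8.0 * pcc, n_grid)
    dens = stats.norm.pdf(s, scale=pcc)
    p_case = special.ndtr((s - thr) / sd_e)
    f_case = dens * p_case
    f_ctrl = dens * (1.0 - p_case)
    w_case = np.trapezoid(f_case, s)
    w_ctrl = np.trapezoid(f_ctrl, s)
    # cumulative control mass below each s (trapezoid running integral)
    ds = s[1] - s[0]
    cum_ctrl = np.concatenate(([0.0], np.cumsum((f_ctrl[1:] + f_ctrl[:-1]) * 0.5 * ds)))
    auc = np.trapezoid(f_case * cum_ctrl, s) / (w_case * w_ctrl)
    return float(min(max(auc, 0.5), 1.0))
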