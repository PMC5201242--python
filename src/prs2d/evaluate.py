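"""Evaluation of PRS methods: cross-validation, improvement tests, diagnostics.

The K-fold driver re-runs the whole discovery pipeline (GWAS scan, clumping,
threshold tuning) inside each training split and evaluates on the held-out
fold, reproducing the design in which the reported R^2 is the maximum over
the threshold grid on the evaluation fold.  Improvement of an alternative
method over the baseline is tested with a paired one-sided t-test across
folds, or a bootstrap normal approximation for a single independent
validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import KFold, StratifiedKFold

from .ld import GenotypePanel, ld_clump
from .scoring import DEFAULT_GRID, ScoreVector, optimize_thresholds, prediction_r2
from .simulate import marginal_gwas
from .sumstats import SnpPartition, SummaryTable

logger = logging.getLogger(__name__)

__all__ = [
    "FoldResult",
    "MethodSpec",
    "parse_method",
    "kfold_prediction",
    "paired_improvement_test",
    "bootstrap_improvement_test",
    "enrichment_fold",
    "enrichment_qq",
    "calibration_slope",
    "risk_stratification",
]


class MethodSpec(NamedTuple):
    """A PRS method label: dimensionality and correction."""

    two_d: bool
    correction: str  # none | lasso | mle

    @property
    def label(self) -> str:
        return f"{'2d' if self.two_d else '1d'}-{self.correction}"


def parse_method(label: str) -> MethodSpec:
    """Parse labels like ``1d-none``, ``2d-lasso``, ``1d-mle``."""
    try:
        dim, corr = label.lower().split("-")
    except ValueError as exc:
        raise ValueError(f"bad method label {label!r}") from exc
    if dim not in ("1d", "2d") or corr not in ("none", "lasso", "mle"):
        raise ValueError(f"bad method label {label!r}")
    return MethodSpec(dim == "2d", corr)


@dataclass(frozen=True)
class FoldResult:
    fold_index: int
    r2_baseline: float
    r2_alternative: float

    @property
    def delta(self) -> float:
        return self.r2_alternative - self.r2_baseline


def _tuned_r2(
    summary: SummaryTable,
    clumped: list[str],
    hp_ids,
    method: MethodSpec,
    panel: GenotypePanel,
    y: np.ndarray,
    grid: Sequence[float],
) -> float:
    partition = (
        SnpPartition.from_hp(clumped, hp_ids) if method.two_d and hp_ids is not None else None
    )
    if method.two_d and partition is None:
        raise ValueError("2D method requires hp_ids")
    _, best, _ = optimize_thresholds(
        summary, clumped, partition, panel, y, grid, method.correction
    )
    return best


def kfold_prediction(
    panel: GenotypePanel,
    y: np.ndarray,
    k: int,
    *,
    baseline: str = "1d-none",
    alternative: str = "2d-lasso",
    hp_ids: Iterable[str] | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    clump_window_bp: int = 500_000,
    clump_r2: float = 0.1,
    binary: bool | None = None,
    seed: int = 0,
) -> list[FoldResult]:
    """K-fold cross-validated comparison of two PRS methods.

    Per fold: marginal GWAS on the training folds, LD-clumping on the
    training panel, then threshold tuning (max R^2 over the grid) of both
    methods on the held-out fold.  Folds are stratified by case status for
    binary phenotypes; everything is deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n = panel.n_samples
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n_samples")
    if binary is None:
        binary = len(np.unique(y)) == 2
    base, alt = parse_method(baseline), parse_method(alternative)
    hp_ids = None if hp_ids is None else frozenset(hp_ids)
    splitter = (
        StratifiedKFold(k, shuffle=True, random_state=seed)
        if binary
        else KFold(k, shuffle=True, random_state=seed)
    )
    results = []
    for fold, (train, test) in enumerate(splitter.split(np.zeros(n), y if binary else None)):
        train_panel = panel.subset_samples(train)
        test_panel = panel.subset_samples(test)
        summary = marginal_gwas(train_panel, y[train])
        clumped = ld_clump(summary, train_panel, clump_window_bp, clump_r2)
        r2_b = _tuned_r2(summary, clumped, hp_ids, base, test_panel, y[test], grid)
        r2_a = _tuned_r2(summary, clumped, hp_ids, alt, test_panel, y[test], grid)
        logger.info("fold %d: baseline %.4f alternative %.4f", fold, r2_b, r2_a)
        results.append(FoldResult(fold, r2_b, r2_a))
    return results


class ImprovementTest(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def paired_improvement_test(folds) -> ImprovementTest:
    """One-sided paired t-test that the alternative beats the baseline.

    T = mean(delta) / sqrt(s^2 / K) with the K-1-denominator sample variance;
    p is the upper tail of t with K-1 degrees of freedom.  All-equal deltas
    are degenerate: p is 0, 1 or 0.5 by the sign of the common mean.
    """
    deltas = np.asarray(
        [f.delta if isinstance(f, FoldResult) else float(f) for f in folds], dtype=float
    )
    k = len(deltas)
    if k < 2:
        raise ValueError("need at least 2 folds")
    mean = deltas.mean()
    s2 = deltas.var(ddof=1)
    if s2 == 0:
        p = 0.0 if mean > 0 else (1.0 if mean < 0 else 0.5)
        return ImprovementTest(np.inf * np.sign(mean) if mean else 0.0, p, True)
    t = mean / np.sqrt(s2 / k)
    return ImprovementTest(float(t), float(stats.t.sf(t, df=k - 1)), False)


def bootstrap_improvement_test(
    scores_baseline,
    scores_alt,
    y,
    b: int = 1_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap test of Delta R^2 > 0 on one independent validation set.

    Resamples individuals with replacement ``b`` times, recomputes
    Delta R^2 = R^2(alt) - R^2(baseline) per replicate, and returns
    (observed Delta R^2, one-sided p = 1 - Phi(observed / sd_boot)).
    Degenerate resamples (constant phenotype) are redrawn, capped at 20
    attempts each.
    """
    s0 = scores_baseline.scores if isinstance(scores_baseline, ScoreVector) else np.asarray(scores_baseline, float)
    s1 = scores_alt.scores if isinstance(scores_alt, ScoreVector) else np.asarray(scores_alt, float)
    y = np.asarray(y, dtype=float)
    if not (len(s0) == len(s1) == len(y)):
        raise ValueError("inputs must be aligned")
    if b < 100:
        raise ValueError("need b >= 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    observed = prediction_r2(s1, y) - prediction_r2(s0, y)
    n = len(y)
    boot = np.empty(b)
    for i in range(b):
        for _ in range(20):
            idx = rng.integers(0, n, size=n)
            if np.std(y[idx]) > 0:
                break
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap sample")
        boot[i] = prediction_r2(s1[idx], y[idx]) - prediction_r2(s0[idx], y[idx])
    sd = boot.std(ddof=1)
    if sd == 0:
        p = 0.5 if observed == 0 else (0.0 if observed > 0 else 1.0)
    else:
        p = float(stats.norm.sf(observed / sd))
    return float(observed), p


def enrichment_fold(partition: SnpPartition, causal_ids: Iterable[str]) -> float:
    """Fold enrichment of causal SNPs in S1: |S1 n C| / (|C||S1|/M)."""
    causal = frozenset(causal_ids)
    if not causal <= partition.universe:
        raise ValueError("causal_ids must be contained in the partition universe")
    if not partition.hp or not causal:
        raise ValueError("empty S1 or causal set")
    m = len(partition.universe)
    overlap = len(partition.hp & causal)
    return overlap / (len(causal) * len(partition.hp) / m)


def enrichment_qq(summary: SummaryTable, partition: SnpPartition) -> pd.DataFrame:
    """QQ data per group: -log10 observed P vs -log10 uniform expectations.

    Rows: (group, expected_quantile, observed_neglog10p), with expectations
    -log10(i/(n+1)) for the i-th smallest P in the group.  Empty groups are
    omitted with a warning.  Input should already be restricted to clumped
    SNPs so the uniform null is appropriate.
    """
    df = summary.df
    frames = []
    for name, ids in (("HP", partition.hp), ("LP", partition.lp)):
        p = np.sort(df.loc[df["snp_id"].isin(ids), "p"].to_numpy())
        if p.size == 0:
            logger.warning("enrichment_qq: empty group %s omitted", name)
            continue
        i = np.arange(1, p.size + 1)
        frames.append(
            pd.DataFrame(
                {
                    "group": name,
                    "expected_quantile": -np.log10(i / (p.size + 1)),
                    "observed_neglog10p": -np.log10(p),
                }
            )
        )
    if not frames:
        raise ValueError("both groups empty")
    return pd.concat(frames, ignore_index=True)


def calibration_slope(scores, y) -> tuple[float, float]:
    """(slope, intercept) of phenotype regressed on the score.

    Ordinary least squares for quantitative phenotypes; logistic regression
    (logit scale) for binary ones.  Slope 1 indicates a calibrated score;
    the uncorrected PRS tends to slope < 1 because winner's curse inflates
    its weights.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if s.std() == 0:
        raise ValueError("constant scores cannot be calibrated")
    if len(np.unique(y)) == 2:
        y01 = (y == y.max()).astype(int)
        fit = sm.Logit(y01, sm.add_constant(s)).fit(disp=0)
        return float(fit.params[1]), float(fit.params[0])
    slope, intercept, *_ = stats.linregress(s, y)
    return float(slope), float(intercept)


def risk_stratification(scores, y, top_fraction: float) -> float:
    """Fraction of all cases captured in the top ``top_fraction`` of scores."""
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    y = np.asarray(y)
    cases = y == y.max()
    if not cases.any() or len(np.unique(y)) < 2:
        raise ValueError("need at least one case and one control")
    cut = np.quantile(s, 1.0 - top_fraction)
    return float(np.mean(s[cases] > cut))
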