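"""Building, applying and tuning 1D/2D polygenic risk scores.

A PRS is sum_m w_m I(P_m < alpha) g_im over clumped SNPs with standardized
genotypes; in 2D mode the high-prior set S1 uses threshold alpha1 and the
low-prior set S2 uses alpha2, and winner's-curse correction of the weights is
recomputed at each threshold (selection and correction are simultaneous).

Two scikit-learn style estimators expose the same machinery: `PRSScorer`
(fit learns the validation panel's standardization and builds the weight
vector; transform emits scores) and `ThresholdGridSearch` (fit tunes the
threshold(s) by maximizing prediction R^2 on the given panel/phenotype).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score

from .ld import GenotypePanel
from .shrinkage import correct_effects
from .sumstats import SnpPartition, SummaryTable

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "PRSModel",
    "ScoreVector",
    "PRSScorer",
    "ThresholdGridSearch",
    "build_prs_model",
    "score_samples",
    "prediction_r2",
    "binary_metrics",
    "optimize_thresholds",
    "write_model",
    "read_model",
]

#: default threshold grid, spanning genome-wide significance to no selection
DEFAULT_GRID = (
    5e-8, 1e-7, 5e-7, 1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4,
    1e-3, 5e-3, 0.01, 0.02, 0.03, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0,
)

MODEL_COLUMNS = ["snp_id", "counted_allele", "weight", "group", "source_p"]


@dataclass
class PRSModel:
    """Selected SNPs with (possibly corrected) weights.

    ``entries`` columns: snp_id, counted_allele, weight, group (HP/LP/ALL),
    source_p.  Every entry's source P-value is strictly below its group's
    threshold; weights are the corrected betas under ``method``.
    """

    entries: pd.DataFrame
    alpha1: float
    alpha2: float | None = None
    method: str = "none"

    def __post_init__(self) -> None:
        missing = [c for c in MODEL_COLUMNS if c not in self.entries.columns]
        if missing:
            raise ValueError(f"model entries missing columns: {missing}")
        thr = {"ALL": self.alpha1, "HP": self.alpha1, "LP": self.alpha2}
        for grp, sub in self.entries.groupby("group"):
            t = thr.get(str(grp))
            if t is None or not (sub["source_p"] < t).all():
                raise ValueError(f"entry P-values not strictly below threshold for {grp}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ScoreVector:
    sample_ids: Sequence[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.sample_ids) != len(self.scores):
            raise ValueError("sample_ids and scores length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")


def _select_group(df: pd.DataFrame, alpha: float, method: str, group: str) -> pd.DataFrame:
    sel = df.loc[df["p"] < alpha]
    if sel.empty:
        return pd.DataFrame(columns=MODEL_COLUMNS)
    weights = correct_effects(
        sel["beta"].to_numpy(), sel["se"].to_numpy(), alpha, method
    )
    return pd.DataFrame(
        {
            "snp_id": sel["snp_id"].to_numpy(),
            "counted_allele": sel["effect_allele"].to_numpy(),
            "weight": weights,
            "group": group,
            "source_p": sel["p"].to_numpy(),
        }
    )


def build_prs_model(
    summary: SummaryTable,
    clumped_ids: Iterable[str],
    partition: SnpPartition | None,
    alpha1: float,
    alpha2: float | None = None,
    method: str = "none",
) -> PRSModel:
    """Select SNPs at the threshold(s) and attach corrected weights.

    1D (no partition): all clumped SNPs with P < alpha1, corrected at alpha1.
    2D: HP SNPs at alpha1, LP SNPs at alpha2, each corrected at its own
    threshold.  The partition must cover every clumped SNP.
    """
    clumped = list(clumped_ids)
    idx = summary.indexed()
    missing = [s for s in clumped if s not in idx.index]
    if missing:
        raise ValueError(f"clumped ids absent from summary, e.g. {missing[0]!r}")
    df = idx.loc[clumped]
    if partition is None:
        entries = _select_group(df, alpha1, method, "ALL")
    else:
        if alpha2 is None:
            raise ValueError("2D model requires alpha2")
        not_covered = [s for s in clumped if s not in partition.universe]
        if not_covered:
            raise ValueError(f"partition does not cover clumped SNPs, e.g. {not_covered[0]!r}")
        in_hp = df["snp_id"].isin(partition.hp)
        parts = [
            _select_group(df.loc[in_hp], alpha1, method, "HP"),
            _select_group(df.loc[~in_hp], alpha2, method, "LP"),
        ]
        parts = [p for p in parts if not p.empty]
        if parts:
            entries = pd.concat(parts, ignore_index=True)
        else:
            entries = pd.DataFrame(columns=MODEL_COLUMNS)
    return PRSModel(entries.reset_index(drop=True), alpha1, alpha2, method)


def score_samples(model: PRSModel, panel: GenotypePanel) -> ScoreVector:
    """Per-sample weighted sum of standardized panel genotypes.

    Panel columns are standardized with the panel's own moments; missing
    dosages are mean-imputed (contribute 0).  Weights of SNPs whose counted
    allele is swapped relative to the panel flip sign; SNPs absent from the
    panel are dropped with a logged count (empty model scores are all 0).
    """
    if len(model) == 0:
        return ScoreVector(panel.sample_ids, np.zeros(panel.n_samples))
    entries = model.entries
    in_panel = entries["snp_id"].isin(panel._index)
    n_absent = int((~in_panel).sum())
    if n_absent:
        logger.info("score_samples: %d model SNPs absent from panel", n_absent)
    entries = entries.loc[in_panel]
    if entries.empty:
        raise ValueError("no model SNPs present in the panel")
    cols = panel._index.get_indexer(entries["snp_id"])
    panel_counted = panel.snp_map["counted_allele"].to_numpy()[cols]
    panel_other = panel.snp_map["other_allele"].to_numpy()[cols]
    counted = entries["counted_allele"].to_numpy()
    sign = np.where(counted == panel_counted, 1.0, np.where(counted == panel_other, -1.0, 0.0))
    n_mismatch = int((sign == 0).sum())
    if n_mismatch:
        logger.info("score_samples: %d model SNPs allele-incompatible, dropped", n_mismatch)
    keep = sign != 0
    if not keep.any():
        raise ValueError("no allele-compatible model SNPs in the panel")
    g = panel.standardized(cols[keep])
    w = entries["weight"].to_numpy()[keep] * sign[keep]
    return ScoreVector(panel.sample_ids, g @ w)


def prediction_r2(scores, y) -> float:
    """Squared Pearson correlation between scores and phenotype.

    Accepts a ScoreVector or array; returns 0 for constant scores.  Binary
    phenotypes coded 0/1 give the observational-scale (point-biserial) R^2.
    """
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and phenotype length mismatch")
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    if s.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(s, y)[0, 1]
    return float(r**2)


def binary_metrics(scores, y) -> tuple[float, float]:
    """(AUC, Nagelkerke R^2) of scores against a 0/1 phenotype.

    AUC is the Mann-Whitney probability P(score_case > score_control) with
    ties counted 1/2; Nagelkerke R^2 comes from a logistic regression of y on
    the scores with intercept.  Constant scores give (0.5, 0.0).
    """
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary_metrics requires exactly two classes")
    y01 = (y == classes.max()).astype(int)
    if s.std() == 0:
        return 0.5, 0.0
    auc = float(roc_auc_score(y01, s))
    x = sm.add_constant(s)
    n = len(y01)
    p1 = y01.mean()
    ll0 = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    try:
        ll1 = sm.Logit(y01, x).fit(disp=0).llf
    except Exception:  # perfect separation: likelihood attains its supremum 0
        ll1 = 0.0
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - np.exp(2.0 * ll0 / n)
    return auc, float(np.clip(cox_snell / max_cs, 0.0, 1.0))


class _GroupScores:
    """Scores of one SNP group at every threshold of a grid, computed once.

    SNPs are sorted by ascending P; for each alpha the selected set is the
    strict-prefix P < alpha and weights are re-corrected at that alpha.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        panel: GenotypePanel,
        grid: Sequence[float],
        method: str,
    ) -> None:
        df = df.loc[df["snp_id"].isin(panel._index)].sort_values("p", kind="mergesort")
        self.n_snps = {}
        self.scores = {}
        p = df["p"].to_numpy()
        if df.empty:
            for a in grid:
                self.n_snps[a] = 0
                self.scores[a] = np.zeros(panel.n_samples)
            return
        cols = panel._index.get_indexer(df["snp_id"])
        g = panel.standardized(cols)
        # allele orientation: summary effect allele vs panel counted allele
        counted = panel.snp_map["counted_allele"].to_numpy()[cols]
        sign = np.where(df["effect_allele"].to_numpy() == counted, 1.0, -1.0)
        beta = df["beta"].to_numpy() * sign
        se = df["se"].to_numpy()
        for a in grid:
            k = int(np.searchsorted(p, a, side="left"))  # count of p < a
            self.n_snps[a] = k
            if k == 0:
                self.scores[a] = np.zeros(panel.n_samples)
            else:
                w = correct_effects(beta[:k], se[:k], a, method)
                self.scores[a] = g[:, :k] @ w


def optimize_thresholds(
    summary: SummaryTable,
    clumped_ids: Iterable[str],
    partition: SnpPartition | None,
    panel: GenotypePanel,
    y: np.ndarray,
    grid: Sequence[float] = DEFAULT_GRID,
    method: str = "none",
) -> tuple[tuple[float, float | None], float, pd.DataFrame]:
    """Maximize validation R^2 over the threshold grid.

    Returns ((alpha1, alpha2), best R^2, surface) where the surface is a tidy
    table with columns alpha1, alpha2, r2, n_snps_hp, n_snps_lp (alpha2 and
    n_snps split are NaN/0-padded in 1D mode).  Correction is re-applied at
    every threshold; results are deterministic given identical inputs.
    """
    grid = [float(a) for a in grid]
    if not grid or any(not 0 < a <= 1 for a in grid):
        raise ValueError("grid must be nonempty with entries in (0, 1]")
    y = np.asarray(y, dtype=float)
    clumped = list(clumped_ids)
    df = summary.indexed().loc[lambda d: d["snp_id"].isin(clumped)]

    rows = []
    if partition is None:
        g_all = _GroupScores(df, panel, grid, method)
        for a in grid:
            r2 = prediction_r2(g_all.scores[a], y)
            rows.append((a, np.nan, r2, g_all.n_snps[a], 0))
    else:
        in_hp = df["snp_id"].isin(partition.hp)
        g_hp = _GroupScores(df.loc[in_hp], panel, grid, method)
        g_lp = _GroupScores(df.loc[~in_hp], panel, grid, method)
        for a1 in grid:
            for a2 in grid:
                r2 = prediction_r2(g_hp.scores[a1] + g_lp.scores[a2], y)
                rows.append((a1, a2, r2, g_hp.n_snps[a1], g_lp.n_snps[a2]))
    surface = pd.DataFrame(rows, columns=["alpha1", "alpha2", "r2", "n_snps_hp", "n_snps_lp"])
    best = surface["r2"].idxmax()  # first maximum: deterministic tie-break
    a1 = float(surface.loc[best, "alpha1"])
    a2 = surface.loc[best, "alpha2"]
    a2 = None if pd.isna(a2) else float(a2)
    return (a1, a2), float(surface.loc[best, "r2"]), surface


# ---------------------------------------------------------------------------
# scikit-learn estimator surface


def _as_panel(X) -> GenotypePanel:
    if isinstance(X, GenotypePanel):
        return X
    raise TypeError("X must be a GenotypePanel (dosage matrix + SNP map)")


class PRSScorer(BaseEstimator, TransformerMixin):
    """Polygenic score as a scikit-learn transformer.

    Parameters mirror :func:`build_prs_model`; ``fit`` builds the weight
    vector from the summary statistics and learns the fitted panel's
    per-SNP standardization moments, ``transform`` returns one score per
    sample, ``score`` the prediction R^2 against a phenotype.
    """

    def __init__(
        self,
        summary: SummaryTable = None,
        clumped_ids: Sequence[str] = None,
        hp_ids: Iterable[str] = None,
        alpha1: float = 1.0,
        alpha2: float | None = None,
        method: str = "none",
    ) -> None:
        self.summary = summary
        self.clumped_ids = clumped_ids
        self.hp_ids = hp_ids
        self.alpha1 = alpha1
        self.alpha2 = alpha2
        self.method = method

    def _partition(self, clumped) -> SnpPartition | None:
        if self.hp_ids is None:
            return None
        return SnpPartition.from_hp(clumped, self.hp_ids)

    def fit(self, X, y=None):
        panel = _as_panel(X)
        clumped = (
            list(self.clumped_ids)
            if self.clumped_ids is not None
            else [s for s in self.summary.snp_ids if s in panel._index]
        )
        self.model_ = build_prs_model(
            self.summary, clumped, self._partition(clumped), self.alpha1, self.alpha2, self.method
        )
        entries = self.model_.entries
        in_panel = entries["snp_id"].isin(panel._index)
        entries = entries.loc[in_panel]
        cols = panel._index.get_indexer(entries["snp_id"])
        counted = panel.snp_map["counted_allele"].to_numpy()[cols]
        other = panel.snp_map["other_allele"].to_numpy()[cols]
        sign = np.where(
            entries["counted_allele"].to_numpy() == counted,
            1.0,
            np.where(entries["counted_allele"].to_numpy() == other, -1.0, 0.0),
        )
        keep = sign != 0
        cols, sign = cols[keep], sign[keep]
        x = np.asarray(panel.dosages[:, cols], dtype=float)
        self.columns_ = entries["snp_id"].to_numpy()[keep]
        self.mean_ = np.nanmean(x, axis=0) if x.size else np.zeros(0)
        sd = np.nanstd(x, axis=0) if x.size else np.zeros(0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.weights_ = entries["weight"].to_numpy()[keep] * sign
        return self

    def transform(self, X) -> np.ndarray:
        panel = _as_panel(X)
        if len(self.columns_) == 0:
            return np.zeros(panel.n_samples)
        cols = panel._index.get_indexer(self.columns_)
        if np.any(cols < 0):
            raise ValueError("panel lacks SNPs the scorer was fitted on")
        x = np.asarray(panel.dosages[:, cols], dtype=float)
        x = (x - self.mean_) / self.scale_
        np.nan_to_num(x, copy=False)
        return x @ self.weights_

    def score(self, X, y) -> float:
        return prediction_r2(self.transform(X), y)


class ThresholdGridSearch(BaseEstimator):
    """Tune PRS threshold(s) on validation data, scikit-learn style.

    ``fit(X, y)`` evaluates prediction R^2 on panel ``X`` / phenotype ``y``
    for every grid threshold (1D) or threshold pair (2D when ``hp_ids`` is
    given), re-correcting weights at each threshold, and exposes the argmax
    as ``best_alpha1_``/``best_alpha2_``/``best_score_`` with the full tidy
    surface in ``surface_`` and a refitted scorer in ``best_estimator_``.
    """

    def __init__(
        self,
        summary: SummaryTable = None,
        clumped_ids: Sequence[str] = None,
        hp_ids: Iterable[str] = None,
        grid: Sequence[float] = DEFAULT_GRID,
        method: str = "none",
    ) -> None:
        self.summary = summary
        self.clumped_ids = clumped_ids
        self.hp_ids = hp_ids
        self.grid = grid
        self.method = method

    def fit(self, X, y):
        panel = _as_panel(X)
        clumped = (
            list(self.clumped_ids)
            if self.clumped_ids is not None
            else [s for s in self.summary.snp_ids if s in panel._index]
        )
        partition = None if self.hp_ids is None else SnpPartition.from_hp(clumped, self.hp_ids)
        (a1, a2), best, surface = optimize_thresholds(
            self.summary, clumped, partition, panel, y, self.grid, self.method
        )
        self.best_alpha1_, self.best_alpha2_, self.best_score_ = a1, a2, best
        self.surface_ = surface
        self.best_estimator_ = PRSScorer(
            self.summary, clumped, self.hp_ids, a1, a2, self.method
        ).fit(panel)
        return self

    def transform(self, X) -> np.ndarray:
        return self.best_estimator_.transform(X)

    def score(self, X, y) -> float:
        return self.best_estimator_.score(X, y)


def write_model(model: PRSModel, path) -> None:
    """Serialize as tab-separated entries with a JSON metadata header line."""
    meta = {"alpha1": model.alpha1, "alpha2": model.alpha2, "method": model.method}
    with open(path, "w") as fh:
        fh.write(f"#prs2d-model {json.dumps(meta)}\n")
        model.entries[MODEL_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_model(path) -> PRSModel:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#prs2d-model "):
            raise ValueError(f"{path} is not a PRS model file")
        meta = json.loads(header[len("#prs2d-model "):])
        entries = pd.read_csv(fh, sep="\t")
    return PRSModel(entries, meta["alpha1"], meta["alpha2"], meta["method"])
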