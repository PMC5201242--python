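"""Reading, validation and harmonization of GWAS summary statistics.

The canonical file dialect is tab-separated with header columns
``SNP CHR BP A1 A2 BETA SE P`` and optional ``EAF N``; ``A1`` is the effect
allele.  Odds-ratio columns are converted to log scale on input.  A
:class:`SummaryTable` wraps a validated :class:`pandas.DataFrame` whose rows
satisfy, for every SNP *m*: ``z = beta/se`` and ``p = 2*Phi(-|z|)`` (two-sided
normal P-value), alleles are single ACGT bases and differ, ``se > 0`` and
``p`` in (0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

#: canonical column order for the tab-separated dialect
CANONICAL_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]
OPTIONAL_COLUMNS = ["eaf", "n"]

#: mapping canonical -> header name in the canonical dialect
CANONICAL_DIALECT = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "A1",
    "other_allele": "A2",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "eaf": "EAF",
    "n": "N",
}

_VALID_BASES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
#: below this, a stored P-value is treated as underflowed and recomputed from z
P_FLOOR = 1e-300


class SummaryInputError(ValueError):
    """Raised for unusable summary-statistics input (empty file, no overlap)."""


class SummaryConfigError(ValueError):
    """Raised when the column-mapping config does not match the file."""


def _normal_sf_two_sided(z: np.ndarray) -> np.ndarray:
    """Two-sided normal P-value from a Z-statistic, safe for |z| up to ~1e4.

    Computed through the log survival function so that huge Z-statistics give
    tiny but nonzero floats instead of underflowing to 0.
    """
    z = np.asarray(z, dtype=float)
    logp = np.log(2.0) + special.log_ndtr(-np.abs(z))
    p = np.exp(logp)
    # exp() may still underflow for |z| > ~38; clamp to the smallest positive float
    return np.maximum(p, np.nextafter(0.0, 1.0))


@dataclass
class SummaryTable:
    """Validated per-SNP marginal GWAS results.

    Parameters
    ----------
    df : DataFrame with columns snp_id, chrom, pos, effect_allele,
        other_allele, beta, se, p, z (eaf, n optional), unique snp_id,
        sorted by (chrom, pos).
    trait_type : "quantitative" or "binary"; binary-trait betas are log-odds
        and are treated identically downstream.
    standardized : whether beta is per standard-deviation of genotype.
    """

    df: pd.DataFrame
    trait_type: str = "quantitative"
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"trait_type must be quantitative|binary, got {self.trait_type}")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"SummaryTable missing columns: {missing}")
        if "z" not in self.df.columns:
            self.df = self.df.assign(z=self.df["beta"] / self.df["se"])
        if self.df["snp_id"].duplicated().any():
            dup = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in SummaryTable: {dup!r}")
        self.df = (
            self.df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp_id"]

    def subset(self, snp_ids: Iterable[str]) -> "SummaryTable":
        keep = self.df["snp_id"].isin(set(snp_ids))
        return SummaryTable(self.df.loc[keep].copy(), self.trait_type, self.standardized)

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("snp_id", drop=False)


@dataclass
class SnpPartition:
    """Disjoint high-prior (S1) / low-prior (S2) split of a SNP universe."""

    universe: frozenset
    hp: frozenset
    lp: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        self.hp = frozenset(self.hp)
        if self.lp is None:
            self.lp = self.universe - self.hp
        else:
            self.lp = frozenset(self.lp)
        if not self.hp <= self.universe:
            raise ValueError("hp set not contained in universe")
        if self.hp & self.lp:
            raise ValueError("hp and lp overlap")
        if self.hp | self.lp != self.universe:
            raise ValueError("hp and lp do not cover the universe")

    @classmethod
    def from_hp(cls, universe: Iterable[str], hp: Iterable[str]) -> "SnpPartition":
        """Build a partition restricting ``hp`` to the universe."""
        universe = frozenset(universe)
        return cls(universe, frozenset(hp) & universe)


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Enforce record invariants; returns (validated frame, drop/fix log counts)."""
    counts: dict[str, int] = {}
    n0 = len(df)
    df = df.dropna(subset=[c for c in CANONICAL_COLUMNS if c != "p"])
    counts["missing_fields"] = n0 - len(df)

    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    ok_alleles = (
        df["effect_allele"].isin(_VALID_BASES)
        & df["other_allele"].isin(_VALID_BASES)
        & (df["effect_allele"] != df["other_allele"])
    )
    counts["bad_alleles"] = int((~ok_alleles).sum())
    df = df.loc[ok_alleles]

    se = pd.to_numeric(df["se"], errors="coerce")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    ok_num = se.gt(0) & beta.notna() & np.isfinite(beta) & np.isfinite(se)
    counts["bad_numeric"] = int((~ok_num).sum())
    df = df.loc[ok_num].copy()
    df["beta"] = beta[ok_num]
    df["se"] = se[ok_num]

    df["z"] = df["beta"] / df["se"]
    p_model = _normal_sf_two_sided(df["z"].to_numpy())
    p_in = pd.to_numeric(df["p"], errors="coerce").to_numpy()
    bad_p = ~np.isfinite(p_in) | (p_in <= 0) | (p_in > 1) | (p_in < P_FLOOR)
    inconsistent = ~bad_p & (np.abs(p_in - p_model) > 1e-6)
    counts["p_recomputed_underflow"] = int(bad_p.sum())
    counts["p_recomputed_inconsistent"] = int(inconsistent.sum())
    p_out = np.where(bad_p | inconsistent, p_model, p_in)
    df["p"] = p_out

    df["pos"] = pd.to_numeric(df["pos"]).astype(np.int64)
    df["chrom"] = df["chrom"].astype(str)
    for key, val in counts.items():
        if val:
            logger.info("summary validation: %s -> %d rows affected", key, val)
    return df, counts


def read_summary_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    trait_type: str = "quantitative",
    sep: str = "\t",
    or_scale: bool = False,
) -> SummaryTable:
    """Read a delimited summary-statistics file into a validated SummaryTable.

    ``dialect`` maps canonical field names (snp_id, chrom, pos, effect_allele,
    other_allele, beta, se, p, optionally eaf, n, or_) to header names in the
    file; defaults to the canonical SNP/CHR/BP/A1/A2/BETA/SE/P dialect.  If the
    dialect contains an ``or_`` entry (or ``or_scale=True`` with a ``beta``
    column holding odds ratios), effects are converted to log odds; the SE is
    assumed to already be on the log scale.  Rows violating record invariants
    are dropped with a logged count.
    """
    mapping = dict(CANONICAL_DIALECT)
    if dialect:
        mapping.update(dialect)

    try:
        raw = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SummaryInputError(f"empty summary file: {path}") from exc
    if raw.empty:
        raise SummaryInputError(f"no data rows in summary file: {path}")

    has_or = "or_" in mapping and mapping["or_"] in raw.columns
    required = [c for c in CANONICAL_COLUMNS if not (c == "beta" and has_or)]
    for canon in required:
        col = mapping.get(canon, canon)
        if col not in raw.columns:
            raise SummaryConfigError(
                f"required column {canon!r} (mapped to {col!r}) not found in {path}"
            )

    df = pd.DataFrame({canon: raw[mapping[canon]] for canon in required})
    if has_or:
        df["beta"] = np.log(pd.to_numeric(raw[mapping["or_"]], errors="coerce"))
    elif or_scale:
        df["beta"] = np.log(pd.to_numeric(df["beta"], errors="coerce"))
    for canon in OPTIONAL_COLUMNS:
        col = mapping.get(canon, canon)
        if col in raw.columns:
            df[canon] = pd.to_numeric(raw[col], errors="coerce")

    df, _ = _validate_frame(df)
    if df.empty:
        raise SummaryInputError(f"all rows of {path} failed validation")
    return SummaryTable(df, trait_type=trait_type, standardized=False)


def write_summary_table(table: SummaryTable, path, *, extra_columns: Iterable[str] = ()) -> None:
    """Write in the canonical tab-separated dialect (round-trips with read)."""
    cols = CANONICAL_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in table.df.columns]
    cols += [c for c in extra_columns if c in table.df.columns]
    out = table.df[cols].rename(columns=CANONICAL_DIALECT)
    out.to_csv(path, sep="\t", index=False)


def standardize_betas(
    table: SummaryTable, maf_source: Mapping[str, float], *, strict: bool = False
) -> SummaryTable:
    """Rescale per-allele effects to the standardized-genotype scale.

    beta and se are multiplied by sqrt(2 f (1-f)) with f the SNP's minor/effect
    allele frequency; z and p are unchanged (the Z-statistic is scale free).
    SNPs without a usable MAF are dropped (or raise under ``strict``).
    """
    if table.standardized:
        return table
    df = table.df.copy()
    f = df["snp_id"].map(lambda s: maf_source.get(s, np.nan)).astype(float)
    ok = np.isfinite(f) & (f > 0) & (f <= 0.5)
    if not ok.all():
        n_bad = int((~ok).sum())
        if strict:
            bad = df.loc[~ok, "snp_id"].iloc[0]
            raise SummaryInputError(f"{n_bad} SNPs without valid MAF (e.g. {bad!r})")
        logger.info("standardize_betas: dropping %d SNPs without valid MAF", n_bad)
        df = df.loc[ok]
        f = f[ok]
    scale = np.sqrt(2.0 * f * (1.0 - f))
    df["beta"] = df["beta"] * scale
    df["se"] = df["se"] * scale
    return SummaryTable(df.reset_index(drop=True), table.trait_type, standardized=True)


def harmonize_alleles(summary: SummaryTable, panel_map: pd.DataFrame) -> SummaryTable:
    """Align summary effects to a genotype panel's counted alleles.

    ``panel_map`` needs columns snp_id, counted_allele, other_allele.  SNPs
    matching after an allele swap get their beta/z sign flipped (and eaf
    complemented); strand-ambiguous SNPs (A/T, C/G) and SNPs absent from or
    allele-incompatible with the panel are dropped.  Idempotent: output
    alleles equal the panel's, so a second pass is the identity.
    """
    pm = panel_map.set_index("snp_id")
    df = summary.df.copy()
    in_panel = df["snp_id"].isin(pm.index)
    logger.info("harmonize_alleles: %d SNPs absent from panel", int((~in_panel).sum()))
    df = df.loc[in_panel].copy()
    if df.empty:
        raise SummaryInputError("no SNPs shared between summary and panel")

    ambiguous = [
        (a, b) in _AMBIGUOUS_PAIRS
        for a, b in zip(df["effect_allele"], df["other_allele"])
    ]
    ambiguous = np.asarray(ambiguous)
    logger.info("harmonize_alleles: %d strand-ambiguous SNPs dropped", int(ambiguous.sum()))
    df = df.loc[~ambiguous]

    counted = pm.loc[df["snp_id"], "counted_allele"].to_numpy()
    other = pm.loc[df["snp_id"], "other_allele"].to_numpy()
    same = (df["effect_allele"].to_numpy() == counted) & (df["other_allele"].to_numpy() == other)
    swapped = (df["effect_allele"].to_numpy() == other) & (df["other_allele"].to_numpy() == counted)
    mismatched = ~(same | swapped)
    logger.info("harmonize_alleles: %d allele-mismatched SNPs dropped", int(mismatched.sum()))
    df = df.loc[~mismatched].copy()
    same, swapped = same[~mismatched], swapped[~mismatched]

    flip = swapped
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "z"] = -df.loc[flip, "z"]
    if "eaf" in df.columns:
        df.loc[flip, "eaf"] = 1.0 - df.loc[flip, "eaf"]
    ea = df["effect_allele"].to_numpy().copy()
    oa = df["other_allele"].to_numpy().copy()
    ea[flip], oa[flip] = oa[flip], ea[flip]
    df["effect_allele"], df["other_allele"] = ea, oa
    if df.empty:
        raise SummaryInputError("no harmonizable SNPs between summary and panel")
    return SummaryTable(df.reset_index(drop=True), summary.trait_type, summary.standardized)


def read_snp_list(path) -> frozenset:
    """Plain-text SNP list, one id per line; blank lines ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_snp_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for snp in sorted(ids):
            fh.write(f"{snp}\n")


def write_partition(partition: SnpPartition, hp_path, lp_path) -> None:
    write_snp_list(partition.hp, hp_path)
    write_snp_list(partition.lp, lp_path)
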