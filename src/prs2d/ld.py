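"""Genotype panels, pairwise LD and P-value-guided LD-clumping.

LD is the squared Pearson correlation of allele dosages (PLINK-style allelic
r^2).  Clumping is greedy by ascending P-value: the most significant
unprocessed SNP is retained and every unprocessed SNP on the same chromosome
closer than the window with r^2 at or above the ceiling is removed, so no
retained same-chromosome pair within the window is in LD at the ceiling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["snp_id", "chrom", "pos", "counted_allele", "other_allele"]


class PanelError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """n_samples x m_snps dosage matrix with a SNP map.

    Dosages are counted-allele counts in [0, 2] (possibly fractional for
    imputed data; NaN for missing).  ``snp_map`` has columns snp_id, chrom,
    pos, counted_allele, other_allele (extra columns such as a simulator's
    block id are carried along).  Monomorphic SNPs are flagged and excluded
    from LD computations.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise PanelError("dosages must be a 2-D matrix")
        if self.dosages.shape[1] != len(self.snp_map):
            raise PanelError(
                f"dosage columns ({self.dosages.shape[1]}) != snp_map rows ({len(self.snp_map)})"
            )
        missing = [c for c in MAP_COLUMNS if c not in self.snp_map.columns]
        if missing:
            raise PanelError(f"snp_map missing columns: {missing}")
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(self.dosages.shape[0])]
        elif len(self.sample_ids) != self.dosages.shape[0]:
            raise PanelError("sample_ids length != dosage rows")
        self.snp_map = self.snp_map.reset_index(drop=True)
        self._index = pd.Index(self.snp_map["snp_id"])
        if self._index.has_duplicates:
            raise PanelError("duplicate snp_id in panel map")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> int:
        loc = self._index.get_indexer([snp_id])[0]
        if loc < 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(loc)

    def column_means(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0, dtype=np.float64)

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency, min(mean/2, 1 - mean/2)."""
        m = self.column_means() / 2.0
        return np.minimum(m, 1.0 - m)

    def polymorphic_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            var = np.nanvar(self.dosages, axis=0, dtype=np.float64)
        return var > 0

    def standardized(
        self, columns: np.ndarray | None = None, dtype=np.float64
    ) -> np.ndarray:
        """Dosages standardized to mean 0, variance 1 per SNP.

        Missing dosages are mean-imputed (0 after centering); monomorphic
        columns are returned as all-zero.
        """
        x = self.dosages[:, columns] if columns is not None else self.dosages
        no_missing = np.issubdtype(x.dtype, np.integer)
        x = np.asarray(x, dtype=dtype)
        if no_missing:  # integer dosages cannot hold NaN; skip slow nan-reductions
            mean = x.mean(axis=0)
            sd = x.std(axis=0)
        else:
            mean = np.nanmean(x, axis=0)
            sd = np.nanstd(x, axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        out = (x - mean) / sd
        if not no_missing:
            np.nan_to_num(out, copy=False)
        return out

    def subset_samples(self, rows: np.ndarray) -> "GenotypePanel":
        ids = np.asarray(self.sample_ids)[rows]
        return GenotypePanel(self.dosages[rows], self.snp_map.copy(), list(ids))

    # -- text IO: dosage matrix (samples x SNPs, snp ids as header) + map file
    def write(self, prefix: str) -> None:
        self.snp_map.to_csv(f"{prefix}.map.tsv", sep="\t", index=False)
        dm = pd.DataFrame(self.dosages, columns=self.snp_map["snp_id"])
        dm.insert(0, "sample_id", list(self.sample_ids))
        dm.to_csv(f"{prefix}.dosage.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str) -> "GenotypePanel":
        snp_map = pd.read_csv(f"{prefix}.map.tsv", sep="\t", dtype={"chrom": str})
        dm = pd.read_csv(f"{prefix}.dosage.tsv", sep="\t")
        sample_ids = dm.pop("sample_id").astype(str).tolist()
        dm = dm[snp_map["snp_id"]]
        return cls(dm.to_numpy(dtype=np.float64), snp_map, sample_ids)


def _corr_columns(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over samples nonmissing for both columns."""
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok].astype(np.float64), y[ok].astype(np.float64)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise PanelError("monomorphic SNP in LD computation")
    return float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * sy))


def pairwise_r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float:
    """Squared dosage correlation between two polymorphic SNPs."""
    a = panel.dosages[:, panel.column(snp_a)]
    b = panel.dosages[:, panel.column(snp_b)]
    return _corr_columns(a, b) ** 2


def _r2_one_vs_many(geno_t: np.ndarray, seed_row: int, other_rows: np.ndarray) -> np.ndarray:
    """r^2 of one standardized SNP row against many (no missing data path)."""
    x = geno_t[seed_row]
    r = geno_t[other_rows] @ x / len(x)
    return r**2


def ld_clump(
    summary,
    panel: GenotypePanel,
    window_bp: int = 500_000,
    r2_max: float = 0.1,
) -> list[str]:
    """Greedy P-value-guided clumping; returns retained SNP ids by ascending P.

    Ties in P are broken by (chrom, pos), then snp_id, so the output does not
    depend on input row order.  Post-condition: no retained pair on the same
    chromosome with distance < window_bp has r^2 >= r2_max.
    """
    df = summary.df
    shared = df["snp_id"].isin(panel._index)
    df = df.loc[shared]
    if df.empty:
        raise PanelError("no SNPs shared between summary and panel")
    poly = panel.polymorphic_mask()
    cols = panel._index.get_indexer(df["snp_id"])
    keep_poly = poly[cols]
    df = df.loc[keep_poly.astype(bool)]
    cols = cols[keep_poly]

    chrom_codes = pd.factorize(df["chrom"])[0]
    order = np.lexsort(
        (
            df["snp_id"].to_numpy(),
            df["pos"].to_numpy(),
            chrom_codes,
            df["p"].to_numpy(),
        )
    )
    snp_ids = df["snp_id"].to_numpy()[order]
    chroms = chrom_codes[order]
    pos = df["pos"].to_numpy()[order]
    cols = cols[order]

    # standardize once (float32: plenty for an r^2 threshold test); mean-imputed
    # zeros keep the dot-product correlation exact for complete data and a good
    # approximation under sporadic missingness.  SNP-major layout makes the
    # per-seed neighbor dot products contiguous.
    geno = np.ascontiguousarray(panel.standardized(cols, dtype=np.float32).T)

    n = len(snp_ids)
    # per-chromosome position index so each seed only inspects its window
    by_chrom: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(chroms):
        members = np.nonzero(chroms == c)[0]
        po = np.argsort(pos[members], kind="mergesort")
        by_chrom[int(c)] = (pos[members][po], members[po])

    removed = np.zeros(n, dtype=bool)
    retained: list[str] = []
    for i in range(n):
        if removed[i]:
            continue
        retained.append(str(snp_ids[i]))
        cpos, cidx = by_chrom[int(chroms[i])]
        lo = np.searchsorted(cpos, pos[i] - window_bp + 1, side="left")
        hi = np.searchsorted(cpos, pos[i] + window_bp - 1, side="right")
        idx = cidx[lo:hi]
        idx = idx[(idx > i) & ~removed[idx]]  # only unprocessed SNPs can be removed
        if idx.size:
            r2 = _r2_one_vs_many(geno, i, idx)
            removed[idx[r2 >= r2_max]] = True
    return retained


def _ld_partners(
    panel: GenotypePanel, query_cols: np.ndarray, r2_min: float, window_bp: int
) -> set[int]:
    """Columns of SNPs within window and r^2 >= r2_min of any query column."""
    chroms = panel.snp_map["chrom"].to_numpy()
    pos = panel.snp_map["pos"].to_numpy()
    poly = panel.polymorphic_mask()
    partners: set[int] = set()
    for c in query_cols:
        if not poly[c]:
            continue
        near = (chroms == chroms[c]) & (np.abs(pos - pos[c]) < window_bp) & poly
        near[c] = False
        idx = np.nonzero(near)[0]
        if not idx.size:
            continue
        both = panel.standardized(np.concatenate(([c], idx)))
        r2 = (both[:, 0] @ both[:, 1:] / panel.n_samples) ** 2
        partners.update(idx[r2 >= r2_min].tolist())
    return partners


def expand_hp_set(
    hp_ids: Iterable[str],
    panel: GenotypePanel,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
) -> frozenset:
    """HP ids plus all panel SNPs in high LD with any of them.

    SNPs on the same chromosome, closer than ``window_bp`` and with
    r^2 >= ``r2_min`` against any HP member join the set.  Ids absent from
    the panel are kept but cannot recruit partners.
    """
    hp_ids = frozenset(hp_ids)
    in_panel = [s for s in hp_ids if s in panel._index]
    n_out = len(hp_ids) - len(in_panel)
    if n_out:
        logger.info("expand_hp_set: %d HP ids not in panel", n_out)
    cols = panel._index.get_indexer(in_panel)
    partners = _ld_partners(panel, cols, r2_min, window_bp)
    return hp_ids | {str(panel.snp_map["snp_id"].iloc[c]) for c in partners}


def count_ld_partners(
    panel: GenotypePanel,
    snp: str,
    r2_min: float = 0.8,
    window_bp: int = 1_000_000,
) -> int:
    """Number of other SNPs within window_bp and r^2 >= r2_min of ``snp``."""
    c = panel.column(snp)
    return len(_ld_partners(panel, np.array([c]), r2_min, window_bp))
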