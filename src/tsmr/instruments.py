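"""Instrument construction: significance filtering, greedy LD clumping,
and instrument-strength statistics (per-SNP F, total R-squared, overall F).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryRecord, SummaryStatsTable

__all__ = [
    "LDMatrix",
    "InstrumentStats",
    "select_genomewide",
    "greedy_clump",
    "snp_f_statistic",
    "instrument_r2",
    "overall_f",
    "instrument_stats",
]

log = logging.getLogger(__name__)

GWAS_P_THRESHOLD = 5e-8
CLUMP_R2_DEFAULT = 0.001
CLUMP_WINDOW_KB_DEFAULT = 10_000


@dataclass
class LDMatrix:
    """Squared-correlation (r^2) matrix over an ordered set of SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 shape {self.r2.shape} does not match {k} SNP ids")
        if len(set(self.snp_ids)) != k:
            raise ValueError("duplicate snp_id in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float | None:
        """r^2 between two SNPs, or None if either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != ids:
            raise ValueError("square LD file must have identical row/column SNP ids")
        return cls(snp_ids=ids, r2=df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "LDMatrix":
        """3-column long format (snp_a, snp_b, r2); absent pairs default to 0."""
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 3:
            raise ValueError("long LD format needs columns snp_a, snp_b, r2")
        a, b, v = df.columns[:3]
        ids = sorted(set(df[a].astype(str)) | set(df[b].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        m = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(m, 1.0)
        for sa, sb, r2 in zip(df[a].astype(str), df[b].astype(str), df[v].astype(float)):
            m[idx[sa], idx[sb]] = r2
            m[idx[sb], idx[sa]] = r2
        return cls(snp_ids=ids, r2=m)

    def to_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )


@dataclass
class InstrumentStats:
    n_snps: int
    r2_total: float | None
    f_overall: float | None
    f_per_snp: list[float]


def _record_pval(rec: SummaryRecord) -> float:
    """Reported p-value, or the two-sided normal p implied by beta/se."""
    if rec.pval is not None:
        return rec.pval
    return float(2.0 * stats.norm.sf(abs(rec.beta / rec.se)))


def select_genomewide(
    table: SummaryStatsTable, p_threshold: float = GWAS_P_THRESHOLD
) -> SummaryStatsTable:
    """Keep records with p below the genome-wide threshold, order preserved."""
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must be in (0, 1], got {p_threshold}")
    kept = [r for r in table.records if _record_pval(r) < p_threshold]
    if not kept:
        warnings.warn(
            f"no SNP in {table.trait_name!r} passes p < {p_threshold:g}", stacklevel=2
        )
    return table.with_records(kept)


def greedy_clump(
    table: SummaryStatsTable,
    ld: LDMatrix,
    r2_threshold: float = CLUMP_R2_DEFAULT,
    window_kb: int = CLUMP_WINDOW_KB_DEFAULT,
) -> SummaryStatsTable:
    """Greedy LD clumping: keep the best (lowest-p) SNP, prune its window.

    Repeatedly takes the lowest-p unprocessed record as an index SNP and
    removes every unprocessed record on the same chromosome within
    ``window_kb`` whose r^2 with the index is at or above ``r2_threshold``.
    Ties in p are broken by (chrom, pos, snp_id).  SNPs missing from the LD
    matrix, or lacking chromosome/position, are treated as unlinked and
    retained with a logged warning.
    """
    window_bp = int(window_kb) * 1000

    def sort_key(rec: SummaryRecord):
        return (
            _record_pval(rec),
            rec.chrom if rec.chrom is not None else "",
            rec.pos if rec.pos is not None else -1,
            rec.snp_id,
        )

    order = sorted(table.records, key=sort_key)
    removed: set[str] = set()
    kept: set[str] = set()
    for idx_rec in order:
        if idx_rec.snp_id in removed or idx_rec.snp_id in kept:
            continue
        kept.add(idx_rec.snp_id)
        if idx_rec.snp_id not in ld._index:
            log.warning("SNP %s absent from LD matrix; retained as unlinked", idx_rec.snp_id)
            continue
        if idx_rec.chrom is None or idx_rec.pos is None:
            log.warning("SNP %s lacks chrom/pos; treated as unlinked", idx_rec.snp_id)
            continue
        for other in table.records:
            if other.snp_id in removed or other.snp_id in kept:
                continue
            if other.chrom != idx_rec.chrom or other.pos is None:
                continue
            if abs(other.pos - idx_rec.pos) > window_bp:
                continue
            r2 = ld.lookup(idx_rec.snp_id, other.snp_id)
            if r2 is not None and r2 >= r2_threshold:
                removed.add(other.snp_id)
    return table.with_records([r for r in table.records if r.snp_id in kept])


def snp_f_statistic(beta: float, se: float) -> float:
    """Per-SNP F approximation, (beta / se)^2."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return (beta / se) ** 2


def instrument_r2(table: SummaryStatsTable, method: str = "eaf_beta") -> float:
    """Proportion of exposure variance explained by the instrument.

    ``eaf_beta`` (default) assumes an SD-standardized continuous exposure
    and sums 2 p (1 - p) beta^2 over SNPs.  ``f_approx`` instead sums the
    per-SNP F / (F + n - 2) terms, which requires per-record sample sizes.
    The result is clipped to [0, 1].
    """
    total = 0.0
    if method == "eaf_beta":
        for rec in table.records:
            if rec.eaf is None:
                raise ValueError(f"record {rec.snp_id} lacks eaf; cannot compute R^2")
            total += 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
    elif method == "f_approx":
        for rec in table.records:
            if rec.n is None:
                raise ValueError(f"record {rec.snp_id} lacks n; cannot use f_approx R^2")
            f = snp_f_statistic(rec.beta, rec.se)
            total += f / (f + rec.n - 2)
    else:
        raise ValueError(f"unknown R^2 method {method!r}")
    return float(min(1.0, max(0.0, total)))


def overall_f(r2_total: float, n: int, k: int) -> float:
    """Overall instrument F: r2 (n - k - 1) / ((1 - r2) k)."""
    if not (0.0 <= r2_total < 1.0):
        raise ValueError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1 or n <= k + 1:
        raise ValueError(f"need n > k + 1 >= 2, got n={n}, k={k}")
    return r2_total * (n - k - 1) / ((1.0 - r2_total) * k)


def instrument_stats(table: SummaryStatsTable, n: int | None = None) -> InstrumentStats:
    """Bundle per-SNP F values with total R^2 and the overall F when computable.

    ``n`` defaults to the median per-record sample size when present.  R^2
    (and hence the overall F) is only computed when every record carries a
    frequency; otherwise those fields are None.
    """
    f_per_snp = [snp_f_statistic(r.beta, r.se) for r in table.records]
    r2_total: float | None
    try:
        r2_total = instrument_r2(table)
    except ValueError:
        r2_total = None
    if n is None:
        sizes = [r.n for r in table.records if r.n is not None]
        n = int(np.median(sizes)) if sizes else None
    f_overall = None
    if r2_total is not None and n is not None and n > len(table) + 1:
        f_overall = overall_f(r2_total, n, len(table))
    return InstrumentStats(
        n_snps=len(table), r2_total=r2_total, f_overall=f_overall, f_per_snp=f_per_snp
    )
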