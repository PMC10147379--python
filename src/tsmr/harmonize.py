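"""Harmonization of exposure and outcome summary statistics.

Merges the two tables on SNP id and puts every retained record onto the
exposure's effect-allele orientation.  Strand flips are resolved via allele
complements; palindromic SNPs (A/T or C/G) are kept only when both samples
report an allele frequency and both minor-allele frequencies fall below a
threshold (default 0.3), with orientation inferred from which side of 0.5
each frequency lies on.  Everything else is dropped with an audited status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sumstats import SummaryRecord, SummaryStatsTable

__all__ = ["HarmonizedRecord", "HarmonizedSet", "is_palindromic", "harmonize"]

PALINDROME_MAF_THRESHOLD = 0.3

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUSES = (
    "aligned",
    "flipped",
    "palindromic_kept",
    "dropped_palindromic",
    "dropped_incompatible",
)

_RETAINED = ("aligned", "flipped", "palindromic_kept")


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    for a in (effect_allele, other_allele):
        if a not in _COMPLEMENT:
            raise ValueError(f"allele {a!r} is not one of A/C/G/T")
    pair = {effect_allele, other_allele}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _is_simple_snp(rec: SummaryRecord) -> bool:
    return rec.effect_allele in _COMPLEMENT and rec.other_allele in _COMPLEMENT


@dataclass
class HarmonizedRecord:
    """Exposure/outcome pair for one SNP, in the exposure's orientation."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class HarmonizedSet:
    """The retained, orientation-consistent records one analysis consumes."""

    records: list[HarmonizedRecord]
    audit: dict[str, int]
    exposure_name: str
    outcome_name: str
    outcome_type: str = "binary"

    @property
    def n_snps(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        bx = np.array([r.beta_exp for r in self.records])
        bxse = np.array([r.se_exp for r in self.records])
        by = np.array([r.beta_out for r in self.records])
        byse = np.array([r.se_out for r in self.records])
        return bx, bxse, by, byse

    def subset(self, keep: np.ndarray | list[int]) -> "HarmonizedSet":
        keep_idx = set(int(i) for i in np.atleast_1d(np.asarray(keep)))
        recs = [r for i, r in enumerate(self.records) if i in keep_idx]
        return HarmonizedSet(
            records=recs,
            audit={"subset_of": self.n_snps},
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
        )

    @property
    def scale(self) -> str:
        return "log_or" if self.outcome_type == "binary" else "sd"


def _maf(freq: float) -> float:
    return min(freq, 1.0 - freq)


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_maf_threshold: float = PALINDROME_MAF_THRESHOLD,
) -> HarmonizedSet:
    """Inner-join exposure and outcome records on a common orientation.

    Non-palindromic SNPs: outcome alleles are matched against the exposure
    pair directly, after swapping effect/other (sign of the outcome beta is
    flipped and its frequency reflected), or after strand complementation,
    in that order; anything else is ``dropped_incompatible``.  Palindromic
    SNPs are retained only when both frequencies are present and both MAFs
    are below the threshold; if the two frequencies disagree on which side
    of 0.5 they fall, the outcome beta is flipped.
    """
    for tbl in (exposure, outcome):
        ids = [r.snp_id for r in tbl.records]
        if len(set(ids)) != len(ids):  # defensive; table invariant should hold
            raise ValueError(f"duplicate snp_id in {tbl.trait_name!r}")

    out_by_id = outcome.by_id()
    records: list[HarmonizedRecord] = []
    audit = {s: 0 for s in STATUSES}

    for exp in exposure.records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue

        if not _is_simple_snp(exp) or not _is_simple_snp(out):
            audit["dropped_incompatible"] += 1
            continue

        o_ea, o_oa = out.effect_allele, out.other_allele
        beta_out, eaf_out = out.beta, out.eaf
        exp_pair = (exp.effect_allele, exp.other_allele)

        if is_palindromic(*exp_pair):
            if {o_ea, o_oa} != set(exp_pair):
                audit["dropped_incompatible"] += 1
                continue
            # nominal letter alignment (complement is the identity here)
            if o_ea != exp.effect_allele:
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1.0 - eaf_out
            if exp.eaf is None or eaf_out is None:
                audit["dropped_palindromic"] += 1
                continue
            if (
                _maf(exp.eaf) >= palindrome_maf_threshold
                or _maf(eaf_out) >= palindrome_maf_threshold
            ):
                audit["dropped_palindromic"] += 1
                continue
            # strand check: frequencies must sit on the same side of 0.5
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            status = "palindromic_kept"
        else:
            if {o_ea, o_oa} == set(exp_pair):
                pass
            elif {_COMPLEMENT[o_ea], _COMPLEMENT[o_oa]} == set(exp_pair):
                o_ea, o_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
            else:
                audit["dropped_incompatible"] += 1
                continue
            if o_ea == exp.effect_allele:
                status = "aligned"
            else:
                beta_out = -beta_out
                eaf_out = None if eaf_out is None else 1.0 - eaf_out
                status = "flipped"

        audit[status] += 1
        records.append(
            HarmonizedRecord(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                status=status,
            )
        )

    return HarmonizedSet(
        records=records,
        audit=audit,
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
    )
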