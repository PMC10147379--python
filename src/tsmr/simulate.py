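"""Seeded generator of two-sample GWAS summary statistics with known truth.

The generator works directly on the summary-statistic scale: per-SNP true
exposure effects are drawn to hit a target instrument R^2, estimated
effects add sampling noise with frequency- and sample-size-determined
standard errors, and outcome effects follow a causal slope plus optional
pleiotropy (balanced, directional, or correlated with instrument strength)
on the log-OR scale for a case-control outcome.  Planted outliers,
palindromic alleles, and a block-diagonal LD matrix let every pipeline
stage be exercised without external data.

Reported effect-allele orientations are randomized per SNP (as in real
GWAS), so signed exposure betas are symmetric around zero; pleiotropic
effects are defined in the exposure-increasing orientation and co-flip
with the orientation sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .instruments import LDMatrix
from .sumstats import SummaryRecord, SummaryStatsTable

__all__ = ["SimConfig", "SimTruth", "simulate_two_sample", "scenario_preset", "PRESETS"]

_NONPALINDROMIC_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")


@dataclass
class SimConfig:
    """Generative parameters for one synthetic two-sample dataset."""

    n_snps: int = 50
    n_exposure_sample: int = 300_000
    n_outcome_cases: int = 6_034
    n_outcome_controls: int = 6_585
    causal_beta: float = 0.2
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    prop_invalid: float = 0.0
    n_outliers: int = 0
    outlier_scale: float = 10.0
    maf_range: tuple[float, float] = (0.1, 0.4)
    palindromic_fraction: float = 0.0
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    r2_target: float = 0.04
    outcome_type: str = "binary"
    inside_correlation: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "none" and self.prop_invalid != 0:
            raise ValueError("prop_invalid must be 0 when pleiotropy_mode is 'none'")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ValueError("prop_invalid must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must be in [0, 1]")
        if not (0.0 <= self.r2_target < 1.0):
            raise ValueError(
                f"instrument R^2 target {self.r2_target} infeasible (must be in [0, 1))"
            )
        if self.outcome_type not in ("binary", "continuous"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.n_outliers < 0 or self.n_outliers > self.n_snps:
            raise ValueError("n_outliers must be in [0, n_snps]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_r2_within <= 1.0):
            raise ValueError("ld_r2_within must be in [0, 1]")


@dataclass
class SimTruth:
    """Generative truth attached to a synthetic dataset for recovery tests."""

    causal_beta: float
    gamma: np.ndarray  # true per-SNP exposure effects, table orientation
    alpha: np.ndarray  # true pleiotropic outcome effects, table orientation
    outlier_indices: list[int]
    instrument_r2_true: float
    invalid_indices: list[int] = field(default_factory=list)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(beta / se))


def simulate_two_sample(
    cfg: SimConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, LDMatrix, SimTruth]:
    """Generate (exposure table, outcome table, LD matrix, truth) from cfg."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    het = 2.0 * maf * (1.0 - maf)  # 2p(1-p)

    # exposure-increasing effect magnitudes scaled to the target R^2;
    # bounded away from zero so no instrument is individually negligible
    raw = 0.3 + np.abs(rng.standard_normal(k))
    scale = math.sqrt(cfg.r2_target / float(np.sum(het * raw**2))) if cfg.r2_target > 0 else 0.0
    gamma_mag = raw * scale

    # reported effect-allele orientation is arbitrary per SNP
    orient = rng.choice([-1.0, 1.0], size=k)
    gamma = orient * gamma_mag

    se_exp = 1.0 / np.sqrt(het * cfg.n_exposure_sample)
    gamma_hat = gamma + se_exp * rng.standard_normal(k)

    # pleiotropy in the exposure-increasing orientation, co-flipped below
    alpha_or = np.zeros(k)
    invalid: list[int] = []
    if cfg.pleiotropy_mode != "none" and cfg.prop_invalid > 0:
        n_inv = int(round(cfg.prop_invalid * k))
        invalid = sorted(rng.choice(k, size=n_inv, replace=False).tolist())
        if n_inv:
            if cfg.pleiotropy_mode == "balanced":
                draw = rng.normal(0.0, cfg.pleio_sd, size=n_inv)
            elif cfg.pleiotropy_mode == "directional":
                draw = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n_inv)
            else:  # inside_violating: pleiotropy tracks instrument strength
                g = gamma_mag[invalid]
                z = (g - g.mean()) / (g.std() if g.std() > 0 else 1.0)
                rho = cfg.inside_correlation
                eps = rng.standard_normal(n_inv)
                draw = cfg.pleio_mean + cfg.pleio_sd * (rho * z + math.sqrt(1 - rho**2) * eps)
            alpha_or[invalid] = draw
    alpha = orient * alpha_or

    if cfg.outcome_type == "binary":
        n_total = cfg.n_outcome_cases + cfg.n_outcome_controls
        n_eff = cfg.n_outcome_cases * cfg.n_outcome_controls / n_total
    else:
        n_total = cfg.n_outcome_cases + cfg.n_outcome_controls
        n_eff = n_total
    se_out = 1.0 / np.sqrt(het * n_eff)

    gamma_big = cfg.causal_beta * gamma + alpha
    beta_out = gamma_big + se_out * rng.standard_normal(k)

    outlier_idx: list[int] = []
    if cfg.n_outliers > 0:
        candidates = np.setdiff1d(np.arange(k), np.asarray(invalid, dtype=int))
        pool = candidates if candidates.size >= cfg.n_outliers else np.arange(k)
        outlier_idx = sorted(rng.choice(pool, size=cfg.n_outliers, replace=False).tolist())
        # a fixed-direction pleiotropic offset, large relative to the SE
        beta_out[outlier_idx] += orient[outlier_idx] * cfg.outlier_scale * se_out[outlier_idx]

    # allele pairs and frequencies (same underlying population both samples)
    n_pal = int(round(cfg.palindromic_fraction * k))
    pal_mask = np.zeros(k, dtype=bool)
    if n_pal:
        pal_mask[rng.choice(k, size=n_pal, replace=False)] = True
    pair_choices_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=k)
    pair_choices_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=k)
    eaf = np.where(rng.random(k) < 0.5, maf, 1.0 - maf)

    # genomic layout: contiguous LD blocks, one 10 Mb region per block
    block = np.arange(k) // cfg.ld_block_size
    chrom = (block % 22 + 1).astype(int)
    pos = (block // 22) * 10_000_000 + (np.arange(k) % cfg.ld_block_size) * 1_000 + 1

    p_exp = _two_sided_p(gamma_hat, se_exp)
    p_out = _two_sided_p(beta_out, se_out)

    snp_ids = [f"rs{i + 1:06d}" for i in range(k)]
    exp_records: list[SummaryRecord] = []
    out_records: list[SummaryRecord] = []
    for i in range(k):
        ea, oa = (
            _PALINDROMIC_PAIRS[pair_choices_p[i]]
            if pal_mask[i]
            else _NONPALINDROMIC_PAIRS[pair_choices_np[i]]
        )
        common = dict(
            snp_id=snp_ids[i],
            effect_allele=ea,
            other_allele=oa,
            chrom=str(chrom[i]),
            pos=int(pos[i]),
            eaf=float(eaf[i]),
        )
        exp_records.append(
            SummaryRecord(
                beta=float(gamma_hat[i]),
                se=float(se_exp[i]),
                pval=float(max(p_exp[i], 5e-324)),
                n=cfg.n_exposure_sample,
                **common,
            )
        )
        out_records.append(
            SummaryRecord(
                beta=float(beta_out[i]),
                se=float(se_out[i]),
                pval=float(max(p_out[i], 5e-324)),
                n=n_total,
                n_cases=cfg.n_outcome_cases if cfg.outcome_type == "binary" else None,
                **common,
            )
        )

    exposure = SummaryStatsTable(
        records=exp_records,
        trait_name="sim_exposure",
        trait_type="continuous",
        unit_note="per 1 SD of the simulated exposure",
    )
    outcome = SummaryStatsTable(
        records=out_records,
        trait_name="sim_outcome",
        trait_type=cfg.outcome_type,
        unit_note="log-OR" if cfg.outcome_type == "binary" else "SD",
    )

    r2 = np.zeros((k, k))
    np.fill_diagonal(r2, 1.0)
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        if idx.size > 1:
            sub = np.full((idx.size, idx.size), cfg.ld_r2_within)
            np.fill_diagonal(sub, 1.0)
            r2[np.ix_(idx, idx)] = sub
    ld = LDMatrix(snp_ids=snp_ids, r2=r2)

    truth = SimTruth(
        causal_beta=cfg.causal_beta,
        gamma=gamma,
        alpha=alpha,
        outlier_indices=outlier_idx,
        instrument_r2_true=cfg.r2_target,
        invalid_indices=invalid,
    )
    return exposure, outcome, ld, truth


#: documented scenario presets; override any field via scenario_preset(**kw)
PRESETS: dict[str, dict] = {
    # clean instrument, moderate protective-to-harmful range of effects
    "valid": dict(),
    # every SNP pleiotropic, zero-mean: InSIDE holds, Egger intercept ~ 0
    "balanced": dict(pleiotropy_mode="balanced", prop_invalid=1.0, pleio_sd=0.03),
    # 30% of SNPs share a positive pleiotropic mean: biases IVW upward
    "directional": dict(
        pleiotropy_mode="directional", prop_invalid=0.3, pleio_mean=0.05, pleio_sd=0.02
    ),
    # pleiotropy correlated with instrument strength: breaks InSIDE
    "inside_violation": dict(
        pleiotropy_mode="inside_violating", prop_invalid=0.3, pleio_mean=0.05, pleio_sd=0.02
    ),
    # 3 SNPs with large fixed-direction outcome offsets
    "outliers": dict(n_outliers=3, outlier_scale=10.0),
    # mean per-SNP F targeted at ~8, below the conventional threshold of 10
    "weak_instruments": dict(n_exposure_sample=100_000, r2_target=0.0035),
}


def scenario_preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A documented SimConfig by scenario name; unknown names are an error."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(SimConfig(seed=seed), **{**PRESETS[name], **overrides})
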