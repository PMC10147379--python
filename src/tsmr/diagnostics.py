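"""Heterogeneity and outlier diagnostics: Cochran Q and the residual-sum
outlier test (global, per-SNP, and distortion components) with an
outlier-corrected IVW estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import EggerResult, MREstimate, ivw, _oriented
from .harmonize import HarmonizedSet

__all__ = ["QStats", "PressoResult", "cochran_q", "mr_presso"]


@dataclass
class QStats:
    q: float
    df: int
    pval: float


@dataclass
class PressoResult:
    """Residual-sum outlier analysis for one harmonized set.

    ``global_pval`` is the empirical tail probability of the observed
    leave-one-out residual sum against its parametric null; outliers are
    SNPs whose (Bonferroni-adjusted by default) per-SNP empirical p falls
    below the significance threshold.  ``corrected_estimate`` is the IVW
    fit on non-outliers; ``distortion_pval`` compares the shift it induces
    against removals of random subsets of the same size (None when no
    outlier was found).
    """

    global_rss_observed: float
    global_pval: float
    outlier_indices: list[int]
    per_snp_pvals: np.ndarray
    corrected_estimate: MREstimate
    distortion_pval: float | None
    n_distributions: int
    seed: int


def cochran_q(hset: HarmonizedSet, fitted: MREstimate | EggerResult) -> QStats:
    """Cochran heterogeneity statistic of the per-SNP effects around a fit.

    Q = sum over SNPs of (beta_out - predicted)^2 / se_out^2 with the
    prediction slope*beta_exp (IVW/Wald; df = k - 1) or
    intercept + slope*beta_exp on Egger-oriented records (df = k - 2).
    """
    k = hset.n_snps
    if isinstance(fitted, EggerResult):
        bx, _, by, byse = _oriented(hset)
        pred = fitted.intercept.beta + fitted.slope.beta * bx
        df = k - 2
    else:
        bx, _, by, byse = hset.arrays()
        pred = fitted.beta * bx
        df = k - 1
    if df <= 0:
        raise ValueError(f"Q undefined: df = {df} with {k} SNPs")
    q = float(np.sum((by - pred) ** 2 / byse**2))
    return QStats(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW slope excluding each SNP in turn (vectorized over SNPs)."""
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(
    hset: HarmonizedSet,
    n_distributions: int = 1000,
    sig_threshold: float = 0.05,
    seed: int = 0,
    outlier_adjustment: str = "bonferroni",
) -> PressoResult:
    """Residual-sum outlier detection and correction.

    Observed statistic: each SNP's weighted squared residual from the IVW
    fit that excludes it, summed over SNPs.  The null is built from
    ``n_distributions`` parametric datasets (both betas resampled from
    their sampling distributions around the leave-one-out fit, seeded);
    the global p is the smoothed tail proportion.  Per-SNP p-values are
    raw empirical tail proportions of each SNP's own residual (so a clear
    outlier can reach p = 0), Bonferroni-adjusted across SNPs unless
    ``outlier_adjustment="none"``.  The corrected estimate is the IVW fit
    without outliers; with none found it equals the full IVW and the
    distortion p is None.
    """
    if outlier_adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown outlier_adjustment {outlier_adjustment!r}")
    k = hset.n_snps
    if k < 4:
        raise ValueError(f"outlier analysis needs at least 4 SNPs, got {k}")
    rng = np.random.default_rng(seed)
    bx, bxse, by, byse = _oriented(hset)
    w = 1.0 / byse**2

    beta_loo = np.atleast_1d(np.squeeze(_loo_slopes(bx, by, w)))
    obs_res2 = w * (by - beta_loo * bx) ** 2
    rss_obs = float(obs_res2.sum())

    B = int(n_distributions)
    bx_sim = bx[None, :] + bxse[None, :] * rng.standard_normal((B, k))
    mu_out = beta_loo * bx  # expected outcome beta under the no-pleiotropy LOO fit
    by_sim = mu_out[None, :] + byse[None, :] * rng.standard_normal((B, k))
    beta_loo_sim = _loo_slopes(bx_sim, by_sim, w[None, :])
    sim_res2 = w[None, :] * (by_sim - beta_loo_sim * bx_sim) ** 2
    rss_sim = sim_res2.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (B + 1))
    per_snp = np.mean(sim_res2 >= obs_res2[None, :], axis=0)
    adjusted = np.minimum(1.0, per_snp * k) if outlier_adjustment == "bonferroni" else per_snp
    outliers = [int(i) for i in np.flatnonzero(adjusted < sig_threshold)]

    full = ivw(hset)
    if not outliers or k - len(outliers) < 2:
        if outliers:  # pragma: no cover - degenerate, nearly-all-outlier case
            warnings.warn("too few non-outliers for a corrected fit; keeping full IVW")
        return PressoResult(
            global_rss_observed=rss_obs,
            global_pval=global_pval,
            outlier_indices=outliers,
            per_snp_pvals=per_snp,
            corrected_estimate=full,
            distortion_pval=None,
            n_distributions=B,
            seed=seed,
        )

    keep = np.setdiff1d(np.arange(k), np.asarray(outliers))
    corrected = ivw(hset.subset(keep))

    # distortion: is the outlier-driven shift larger than removing random
    # subsets of the same size?
    m = len(outliers)
    d_obs = abs(corrected.beta - full.beta)
    shifts = np.empty(B)
    s_xx = np.sum(w * bx * bx)
    s_xy = np.sum(w * bx * by)
    for b in range(B):
        drop = rng.choice(k, size=m, replace=False)
        sub_xx = s_xx - np.sum(w[drop] * bx[drop] ** 2)
        sub_xy = s_xy - np.sum(w[drop] * bx[drop] * by[drop])
        shifts[b] = abs(sub_xy / sub_xx - full.beta)
    distortion_pval = float((1 + np.sum(shifts >= d_obs)) / (B + 1))

    return PressoResult(
        global_rss_observed=rss_obs,
        global_pval=global_pval,
        outlier_indices=outliers,
        per_snp_pvals=per_snp,
        corrected_estimate=corrected,
        distortion_pval=distortion_pval,
        n_distributions=B,
        seed=seed,
    )
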