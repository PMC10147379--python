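"""Causal-effect estimators for two-sample Mendelian randomization.

Given a harmonized set of per-SNP exposure (``beta_exp``, ``se_exp``) and
outcome (``beta_out``, ``se_out``) associations, this module provides:

* per-SNP Wald ratios,
* the inverse-variance-weighted (IVW) estimator — weighted regression of
  outcome on exposure betas through the origin, with a multiplicative
  random-effects standard error by default,
* MR-Egger regression (slope + pleiotropy intercept),
* the weighted median and weighted mode robust estimators with
  parametric-bootstrap standard errors,
* the I2 statistic quantifying exposure-measurement error (the "NOME"
  diagnostic), and a simulation-extrapolation (SIMEX) corrected MR-Egger
  for when it is violated.

All stochastic operations take an explicit seed and are reproducible
bit-for-bit.  Estimators are invariant to re-orienting any record (both
betas negated): IVW and the Wald ratio are algebraically so, and the
Egger/median/mode fits first orient every record to a non-negative
exposure beta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .harmonize import HarmonizedRecord, HarmonizedSet

__all__ = [
    "MREstimate",
    "EggerIntercept",
    "EggerResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "i2_gx",
    "simex_egger",
]

Z95 = float(stats.norm.ppf(0.975))

SIMEX_LAMBDAS_DEFAULT = (0.0, 0.5, 1.0, 1.5, 2.0)


@dataclass
class MREstimate:
    """A causal-effect estimate on the beta scale.

    ``scale`` records the outcome scale: ``log_or`` (binary outcome; the
    exponentiated estimate is an odds ratio) or ``sd``.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale: str = "log_or"

    def as_odds_ratio(self) -> tuple[float, float, float]:
        if self.scale != "log_or":
            raise ValueError("odds-ratio conversion only valid on the log_or scale")
        return math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class EggerIntercept:
    beta: float
    se: float
    pval: float
    n_snps: int


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: EggerIntercept


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _estimate(method: str, beta: float, se: float, pval: float, n_snps: int, scale: str) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(pval),
        n_snps=int(n_snps),
        scale=scale,
    )


def _oriented(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Arrays with every record flipped so beta_exp >= 0."""
    bx, bxse, by, byse = hset.arrays()
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, bxse, by * sign, byse


def wald_ratio(
    rec: HarmonizedRecord, se_method: str = "first_order", scale: str = "log_or"
) -> MREstimate:
    """Single-SNP causal estimate: outcome beta over exposure beta.

    ``first_order`` propagates only the outcome SE (se_out / |beta_exp|);
    ``second_order`` adds the exposure-beta sampling term of the delta
    method.
    """
    if rec.beta_exp == 0:
        raise ValueError(f"beta_exp is zero for {rec.snp_id}; Wald ratio undefined")
    beta = rec.beta_out / rec.beta_exp
    if se_method == "first_order":
        se = rec.se_out / abs(rec.beta_exp)
    elif se_method == "second_order":
        se = math.sqrt(
            rec.se_out**2 / rec.beta_exp**2
            + rec.beta_out**2 * rec.se_exp**2 / rec.beta_exp**4
        )
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return _estimate("wald", beta, se, _normal_p(beta, se), 1, scale)


def ivw(hset: HarmonizedSet, model: str = "multiplicative_random_effects") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of beta_out on beta_exp through the origin with
    weights 1/se_out^2; the slope equals the inverse-variance-weighted mean
    of the Wald ratios.  Under the default multiplicative random-effects
    model the fixed-effects SE is inflated by the residual scale when that
    exceeds 1; ``fixed_effects`` forces the scale to 1.  A single-SNP set
    degenerates to the Wald ratio.
    """
    if model not in ("multiplicative_random_effects", "fixed_effects"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = hset.n_snps
    if k == 0:
        raise ValueError("empty harmonized set")
    bx, bxse, by, byse = hset.arrays()
    if np.all(bx == 0):
        raise ValueError("all exposure betas are zero; IVW undefined")
    if k == 1:
        w = wald_ratio(hset.records[0], scale=hset.scale)
        return replace(w, method="ivw")
    w = 1.0 / byse**2
    s_xx = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / s_xx
    se = math.sqrt(1.0 / s_xx)
    if model == "multiplicative_random_effects":
        resid_scale = float(np.sum(w * (by - beta * bx) ** 2)) / (k - 1)
        se *= math.sqrt(max(1.0, resid_scale))
    return _estimate("ivw", beta, se, _normal_p(beta, se), k, hset.scale)


def _egger_fit(
    bx: np.ndarray, by: np.ndarray, byse: np.ndarray
) -> tuple[float, float, float, float]:
    """Weighted Egger regression on pre-oriented arrays.

    Returns (slope, intercept, se_slope, se_intercept) with the residual
    scale floored at 1, mirroring the multiplicative random-effects IVW.
    """
    k = bx.size
    w = 1.0 / byse**2
    sw = w.sum()
    swx = float(np.sum(w * bx))
    swxx = float(np.sum(w * bx * bx))
    det = sw * swxx - swx * swx
    # no slope identifiability when the oriented exposure betas coincide
    if det <= 0 or not np.isfinite(det) or det < 1e-14 * sw * swxx:
        raise ValueError("exposure betas are collinear after orientation; Egger fit singular")
    swy = float(np.sum(w * by))
    swxy = float(np.sum(w * bx * by))
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    scale = max(1.0, sigma2)
    se_slope = math.sqrt(scale * sw / det)
    se_intercept = math.sqrt(scale * swxx / det)
    return slope, intercept, se_slope, se_intercept


def mr_egger(hset: HarmonizedSet) -> EggerResult:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Records are first oriented so beta_exp >= 0 (the fit is not
    orientation-invariant otherwise).  The intercept estimates the average
    directional pleiotropic effect; p-values use a t distribution with
    k - 2 degrees of freedom.
    """
    k = hset.n_snps
    if k < 3:
        raise ValueError(f"MR-Egger needs at least 3 SNPs, got {k}")
    bx, bxse, by, byse = _oriented(hset)
    slope, intercept, se_s, se_i = _egger_fit(bx, by, byse)
    df = k - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_s), df))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_i), df))
    return EggerResult(
        slope=_estimate("egger_slope", slope, se_s, p_slope, k, hset.scale),
        intercept=EggerIntercept(beta=float(intercept), se=float(se_i), pval=p_int, n_snps=k),
    )


def _ratio_weights(bx: np.ndarray, byse: np.ndarray) -> np.ndarray:
    """First-order inverse-variance weights of the Wald ratios, normalized."""
    w = bx**2 / byse**2
    return w / w.sum()


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    p = np.cumsum(w) - 0.5 * w
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def _finite_ratio_mask(bx: np.ndarray) -> np.ndarray:
    return bx != 0


def _bootstrap_se(
    point_fn,
    bx: np.ndarray,
    bxse: np.ndarray,
    by: np.ndarray,
    byse: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + bxse * rng.standard_normal(bx.size)
        by_b = by + byse * rng.standard_normal(by.size)
        ok = _finite_ratio_mask(bx_b)
        est[b] = point_fn(by_b[ok] / bx_b[ok], _ratio_weights(bx_b[ok], byse[ok]))
    return float(np.std(est, ddof=1))


def _robust_estimator(
    hset: HarmonizedSet, point_fn, method: str, n_boot: int, seed: int
) -> MREstimate:
    k = hset.n_snps
    if k < 3:
        raise ValueError(f"{method} needs at least 3 SNPs, got {k}")
    if 0 < n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; SE will be noisy", stacklevel=3)
    bx, bxse, by, byse = _oriented(hset)
    ok = _finite_ratio_mask(bx)
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} zero-exposure-beta SNP(s)", stacklevel=3)
        bx, bxse, by, byse = bx[ok], bxse[ok], by[ok], byse[ok]
    beta = point_fn(by / bx, _ratio_weights(bx, byse))
    if n_boot <= 0:
        return _estimate(method, beta, float("nan"), float("nan"), int(ok.sum()), hset.scale)
    se = _bootstrap_se(point_fn, bx, bxse, by, byse, n_boot, seed)
    return _estimate(method, beta, se, _normal_p(beta, se), int(ok.sum()), hset.scale)


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator.

    The estimate interpolates the weighted empirical CDF of the per-SNP
    Wald ratios at probability 0.5, with weights proportional to
    beta_exp^2 / se_out^2.  It is consistent when at least half of the
    weight comes from valid instruments.  The SE is a parametric bootstrap
    (``n_boot`` resamples of both betas from their sampling distributions);
    ``n_boot=0`` skips it and returns NaN SE/p.
    """
    return _robust_estimator(hset, _weighted_median, "weighted_median", n_boot, seed)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    k = ratios.size
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * k ** (-0.2)


def _make_mode_fn(phi: float, n_grid: int = 512):
    def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray) -> float:
        h = _mode_bandwidth(ratios, phi)
        if not np.isfinite(h) or h <= 0:
            # degenerate spread: fall back to the weighted median
            return _weighted_median(ratios, weights)
        lo, hi = ratios.min() - 2 * h, ratios.max() + 2 * h
        grid = np.linspace(lo, hi, n_grid)
        dens = _kde(grid, ratios, weights, h)
        i = int(np.argmax(dens))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            lambda x: -_kde(np.array([x]), ratios, weights, h)[0],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    return _weighted_mode_point


def _kde(x: np.ndarray, ratios: np.ndarray, weights: np.ndarray, h: float) -> np.ndarray:
    z = (x[:, None] - ratios[None, :]) / h
    return (weights[None, :] * np.exp(-0.5 * z * z)).sum(axis=1) / (h * math.sqrt(2 * math.pi))


def weighted_mode(
    hset: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-mode estimator.

    The per-SNP Wald ratios are smoothed with a normal kernel (bandwidth =
    ``phi`` times a modified Silverman rule) using the same weights as the
    weighted median; the estimate is the density argmax, the SE a
    parametric bootstrap.  Consistent when the largest weighted cluster of
    SNPs is valid.
    """
    return _robust_estimator(hset, _make_mode_fn(phi), "weighted_mode", n_boot, seed)


def i2_gx(hset: HarmonizedSet) -> float:
    """I2 statistic for exposure-measurement error (NOME diagnostic).

    Cochran-type heterogeneity of the exposure betas with weights
    1/se_exp^2; values near 1 indicate negligible measurement error, and
    values below ~0.9 conventionally trigger the SIMEX-corrected Egger fit.
    In the large-sample limit I2 approximates (F - 1) / F at the mean
    per-SNP F.
    """
    k = hset.n_snps
    if k < 2:
        raise ValueError("I2 needs at least 2 SNPs")
    bx, bxse, _, _ = hset.arrays()
    w = 1.0 / bxse**2
    mean = float(np.sum(w * bx) / np.sum(w))
    q = float(np.sum(w * (bx - mean) ** 2))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (k - 1)) / q)


def simex_egger(
    hset: HarmonizedSet,
    lambdas: tuple[float, ...] = SIMEX_LAMBDAS_DEFAULT,
    n_sim: int = 1000,
    seed: int = 0,
    extrapolation: str = "quadratic",
) -> EggerResult:
    """Simulation-extrapolation corrected MR-Egger.

    For each lambda > 0, noise of variance lambda * se_exp^2 is added to
    the exposure betas ``n_sim`` times, the Egger regression is refit on
    each replicate, and coefficients are averaged.  A polynomial in lambda
    (quadratic by default, linear as fallback) is then extrapolated to
    lambda = -1, the zero-measurement-error point.  Variances are
    extrapolated the same way (a simplification of the full SIMEX variance
    estimator, documented here); when the extrapolated variance is not
    positive the lambda = 0 variance is used instead.  With no exposure
    measurement error, or a lambda grid containing only 0, the result is
    the plain Egger fit relabelled ``egger_simex``.
    """
    if extrapolation not in ("quadratic", "linear"):
        raise ValueError(f"unknown extrapolation {extrapolation!r}")
    base = mr_egger(hset)
    k = hset.n_snps
    bx, bxse, by, byse = _oriented(hset)
    pos = sorted({float(l) for l in lambdas if l > 0})
    if np.all(bxse == 0) or not pos:
        slope = replace(base.slope, method="egger_simex")
        return EggerResult(slope=slope, intercept=base.intercept)

    lam_grid = [0.0] + pos
    mean_slope = [base.slope.beta]
    mean_int = [base.intercept.beta]
    mean_var_s = [base.slope.se**2]
    mean_var_i = [base.intercept.se**2]
    rng = np.random.default_rng(seed)
    for lam in pos:
        s_acc = np.empty(n_sim)
        i_acc = np.empty(n_sim)
        vs_acc = np.empty(n_sim)
        vi_acc = np.empty(n_sim)
        sd = np.sqrt(lam) * bxse
        for r in range(n_sim):
            bx_r = bx + sd * rng.standard_normal(k)
            sign = np.where(bx_r < 0, -1.0, 1.0)
            s, i, ses, sei = _egger_fit(bx_r * sign, by * sign, byse)
            s_acc[r], i_acc[r], vs_acc[r], vi_acc[r] = s, i, ses**2, sei**2
        mean_slope.append(float(s_acc.mean()))
        mean_int.append(float(i_acc.mean()))
        mean_var_s.append(float(vs_acc.mean()))
        mean_var_i.append(float(vi_acc.mean()))

    deg = 2 if (extrapolation == "quadratic" and len(lam_grid) >= 3) else 1
    lam_arr = np.asarray(lam_grid)

    def _extrapolate(values: list[float]) -> float:
        try:
            coef = np.polyfit(lam_arr, np.asarray(values), deg)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError("SIMEX extrapolation fit is singular") from exc
        return float(np.polyval(coef, -1.0))

    slope_c = _extrapolate(mean_slope)
    int_c = _extrapolate(mean_int)
    var_s = _extrapolate(mean_var_s)
    var_i = _extrapolate(mean_var_i)
    se_s = math.sqrt(var_s) if var_s > 0 else base.slope.se
    se_i = math.sqrt(var_i) if var_i > 0 else base.intercept.se
    df = k - 2
    p_s = float(2.0 * stats.t.sf(abs(slope_c / se_s), df)) if se_s > 0 else 0.0
    p_i = float(2.0 * stats.t.sf(abs(int_c / se_i), df)) if se_i > 0 else 0.0
    return EggerResult(
        slope=_estimate("egger_simex", slope_c, se_s, p_s, k, hset.scale),
        intercept=EggerIntercept(beta=int_c, se=se_i, pval=p_i, n_snps=k),
    )
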