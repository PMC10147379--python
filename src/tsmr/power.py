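"""Analytic power for binary-outcome two-sample MR.

Uses the standard non-centrality approximation for a case-control outcome:
NCP = n * R2 * K(1-K) * log(OR)^2, where K is the case fraction and R2 the
variance in the exposure explained by the instrument.  Power is the
two-sided normal tail probability at the given alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

__all__ = ["PowerInputs", "mr_power_binary", "detectable_or", "power_grid"]


@dataclass
class PowerInputs:
    n_total: int
    case_fraction: float
    r2_instrument: float
    or_alt: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"n_total must be positive, got {self.n_total}")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError(f"case_fraction must be in (0, 1), got {self.case_fraction}")
        if not (0.0 < self.r2_instrument < 1.0):
            raise ValueError(f"r2_instrument must be in (0, 1), got {self.r2_instrument}")
        if self.or_alt <= 0:
            raise ValueError(f"or_alt must be positive, got {self.or_alt}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def mr_power_binary(inp: PowerInputs) -> float:
    """Two-sided power to detect ``or_alt`` at ``alpha``."""
    inp.validate()
    k = inp.case_fraction
    ncp = inp.n_total * inp.r2_instrument * k * (1.0 - k) * math.log(inp.or_alt) ** 2
    z = stats.norm.ppf(1.0 - inp.alpha / 2.0)
    root = math.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))


def detectable_or(
    n_total: int,
    case_fraction: float,
    r2_instrument: float,
    target_power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest odds ratio >= 1 detectable at the target power (bisection)."""
    if not (alpha < target_power < 1.0):
        raise ValueError(f"target_power must be in (alpha, 1), got {target_power}")

    def power_at(or_alt: float) -> float:
        return mr_power_binary(
            PowerInputs(n_total, case_fraction, r2_instrument, or_alt, alpha)
        )

    hi = 1000.0
    if power_at(hi) < target_power:
        raise ValueError("no odds ratio below 1000 reaches the target power")
    lo = 1.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def power_grid(inp: PowerInputs, ors: list[float]) -> list[dict]:
    """Power at each odds ratio, for tabular export."""
    rows = []
    for or_alt in ors:
        rows.append(
            {
                "or_alt": or_alt,
                "n_total": inp.n_total,
                "case_fraction": inp.case_fraction,
                "r2_instrument": inp.r2_instrument,
                "alpha": inp.alpha,
                "power": mr_power_binary(replace(inp, or_alt=or_alt)),
            }
        )
    return rows
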