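"""Analytic power for summary-data Mendelian randomization.

Uses the standard normal approximation: the MR z-statistic has
non-centrality

    ncp = |theta| * sqrt(n * r2_gx * K * (1 - K))   (binary outcome)
    ncp = |theta| * sqrt(n * r2_gx)                 (continuous outcome)

where n is the outcome sample size, K the case fraction, r2_gx the
proportion of exposure variance explained by the instruments, and theta the
true effect per SD of exposure (log odds ratio for binary outcomes).  Power
at two-sided level alpha is approximated one-tailed as

    power = Phi(ncp - z_{1 - alpha/2}),

so a null effect gives power alpha/2 — the convention of the online
calculators commonly used for MR study design.  The formula treats the
genetic score as a single fixed instrument; it ignores exposure-side
estimation error and LD-induced efficiency loss, both of which reduce
effective r2_gx.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from scipy.stats import norm


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of an MR power calculation.

    ``case_fraction`` must be present for binary outcomes and absent
    (``None``) for continuous outcomes in SD units.
    """

    n: int
    r2_gx: float
    theta: float
    case_fraction: float | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 < self.r2_gx < 1):
            raise ValueError("r2_gx must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")


def _power_from_ncp(ncp: float, alpha: float) -> float:
    return float(norm.cdf(ncp - norm.ppf(1 - alpha / 2)))


def power_binary(spec: PowerSpec) -> float:
    """Power to detect ``theta`` (log OR per SD exposure) for a binary outcome."""
    if spec.case_fraction is None:
        raise ValueError("power_binary requires case_fraction")
    k = spec.case_fraction
    ncp = abs(spec.theta) * (spec.n * spec.r2_gx * k * (1 - k)) ** 0.5
    return _power_from_ncp(ncp, spec.alpha)


def power_continuous(spec: PowerSpec) -> float:
    """Power for a continuous outcome in SD units."""
    if spec.case_fraction is not None:
        raise ValueError("power_continuous requires case_fraction to be absent")
    ncp = abs(spec.theta) * (spec.n * spec.r2_gx) ** 0.5
    return _power_from_ncp(ncp, spec.alpha)


def power_curve(spec: PowerSpec, n_grid: Sequence[int]) -> list[tuple[int, float]]:
    """Evaluate the appropriate power function over a grid of sample sizes."""
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    fn = power_binary if spec.case_fraction is not None else power_continuous
    return [(int(n), fn(replace(spec, n=int(n)))) for n in n_grid]
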