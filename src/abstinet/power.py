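"""Sample-size and power calculations for unbalanced two-sample designs.

The study design compares a small abstinent group against a much larger
non-abstinent group, so all calculations are parameterised by the
allocation ratio ``r = n1 / n2``.  Power for the two-sided two-sample
t test uses the noncentral t distribution with noncentrality
``ncp = d * sqrt(n1 * n2 / (n1 + n2))``, which reproduces the conventions
of standard power software; a normal approximation is exposed for
cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a required-sample-size calculation.

    effect_size
        standardized mean difference (Cohen's d), > 0.
    alpha
        two-sided type-I error rate.
    power
        target power in (0, 1).
    ratio
        allocation ratio n1/n2 between the smaller and larger group.
    """

    effect_size: float
    alpha: float = 0.05
    power: float = 0.95
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if not self.effect_size > 0:
            raise ValueError("effect_size must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not self.ratio > 0:
            raise ValueError("ratio must be positive")


def allocation_ratio(p_group1: float, p_group2: float, digits: int = 2) -> float:
    """Allocation ratio of two group proportions, rounded for reporting.

    ``allocation_ratio(13.8, 86.2)`` -> ``0.16``, the abstinent /
    non-abstinent split taken over from three-year smoking-abstinence
    outcomes.
    """
    if p_group2 == 0:
        raise ZeroDivisionError("second group proportion must be nonzero")
    if p_group1 <= 0 or p_group2 < 0:
        raise ValueError("proportions must be positive")
    return round(p_group1 / p_group2, digits)


def achieved_power(
    d: float, alpha: float, n1: int, n2: int, approx: bool = False
) -> float:
    """Power of the two-sided two-sample t test at the given group sizes.

    Uses the noncentral t distribution with ``df = n1 + n2 - 2`` and
    ``ncp = d * sqrt(n1 n2 / (n1 + n2))``; with ``approx=True`` a normal
    approximation replaces the noncentral t.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    ncp = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    if approx:
        return float(
            stats.norm.sf(tcrit - ncp) + stats.norm.cdf(-tcrit - ncp)
        )
    return float(
        stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def required_total_n(spec: PowerSpec, n_cap: int = 10_000_000) -> int:
    """Smallest total sample size meeting the target power at the ratio.

    The larger group size ``n2`` is scanned upward; at each candidate the
    smaller group is set to ``n1 = round(r * n2)`` (at least 2) and the
    noncentral-t power evaluated.  The first candidate reaching the
    target fixes the reported total ``n1 + n2``.
    """
    r = spec.ratio
    n2 = 2
    while n2 <= n_cap:
        n1 = max(2, round(r * n2))
        if achieved_power(spec.effect_size, spec.alpha, n1, n2) >= spec.power:
            return n1 + n2
        n2 += 1
    raise ValueError(
        f"no total sample size below cap {n_cap} reaches power {spec.power}"
    )
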