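"""Two-sample t-test power and minimal sample size for animal cohorts.

Power is exact, via the noncentral t distribution: for equal groups of
size n, effect size d (mean difference over common SD), the test
statistic under the alternative is noncentral t with noncentrality
delta = d * sqrt(n/2) and 2n - 2 degrees of freedom.  The cohort-design
question answered here: with d = 2 (e.g. a 1 log10-flux difference
against an SD of 0.5), two-sided alpha 0.05 and 80% power, six animals
per group suffice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.power import TTestIndPower

_ALTERNATIVES = ("two-sided", "larger")


@dataclass(frozen=True)
class PowerSpec:
    """Design inputs: standardized effect size, alpha, target power."""

    effect_size_d: float
    alpha: float = 0.05
    target_power: float = 0.80
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if self.effect_size_d <= 0:
            raise ValueError("effect size d must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not (0 < self.target_power < 1):
            raise ValueError("target power must be in (0,1)")
        if self.alternative not in _ALTERNATIVES:
            raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def power_at_n(spec: PowerSpec, n_per_group: int) -> float:
    """Exact power of the equal-variance two-sample t test at group size n."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    power = float(
        TTestIndPower().power(
            effect_size=spec.effect_size_d,
            nobs1=n_per_group,
            alpha=spec.alpha,
            ratio=1.0,
            alternative=spec.alternative,
        )
    )
    if math.isnan(power):
        # extreme noncentrality underflows the far tail; recompute tail-safe
        df = 2 * n_per_group - 2
        delta = spec.effect_size_d * math.sqrt(n_per_group / 2.0)
        if spec.alternative == "two-sided":
            tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
            upper = stats.nct.sf(tcrit, df, delta)
            lower = stats.nct.cdf(-tcrit, df, delta)
            power = float(np.nan_to_num(upper) + np.nan_to_num(lower))
        else:
            tcrit = stats.t.ppf(1.0 - spec.alpha, df)
            power = float(np.nan_to_num(stats.nct.sf(tcrit, df, delta)))
    return power


def min_n(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest equal group size n >= 2 reaching the target power."""
    n = 2
    while n <= n_max:
        if power_at_n(spec, n) >= spec.target_power:
            return n
        n += 1
    raise ValueError(
        f"target power {spec.target_power} unreachable within n <= {n_max}"
    )
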