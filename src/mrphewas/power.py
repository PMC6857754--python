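"""Analytic power for Mendelian-randomization studies.

Uses the standard non-centrality approximation for an instrumental-variable
test: with N individuals, instrument variance explained R^2, case fraction
K and alternative odds ratio OR per SD of exposure, the two-sided Wald test
at level alpha has power

    Phi( sqrt(N R^2 K (1-K)) |ln OR| - z_{1-alpha/2} )

(the companion continuous-outcome form drops the K(1-K) factor). Power at
the null equals alpha/2: the formula keeps the one-rejection-region-of-two
convention of the reference calculators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05
DEFAULT_R2 = 0.0284


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for a binary-outcome MR power calculation."""

    n_total: int
    n_cases: int
    r2: float = DEFAULT_R2
    or_alt: float = 1.2
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 < self.n_cases < self.n_total:
            raise ValueError("n_cases must lie strictly between 0 and n_total")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must lie strictly in (0,1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


def power_binary(spec: PowerSpec) -> float:
    """Power to detect ``or_alt`` per SD of exposure for a binary outcome."""
    k = spec.case_fraction
    z = stats.norm.ppf(1 - spec.alpha / 2)
    ncp = np.sqrt(spec.n_total * spec.r2 * k * (1 - k)) * abs(np.log(spec.or_alt))
    return float(stats.norm.cdf(ncp - z))


def power_continuous(n: int, r2: float, beta_sd: float,
                     alpha: float = DEFAULT_ALPHA) -> float:
    """Power to detect an effect of ``beta_sd`` outcome-SD per exposure-SD."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie strictly in (0,1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    z = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.cdf(np.sqrt(n * r2) * abs(beta_sd) - z))


def min_cases_for_power(target_power: float, or_alt: float,
                        r2: float = DEFAULT_R2,
                        case_control_ratio: float = 5.0,
                        alpha: float = DEFAULT_ALPHA) -> int:
    """Smallest case count reaching ``target_power`` at a fixed case:control ratio.

    With ratio controls per case, K = 1/(1+ratio) and N = cases x (1+ratio);
    the count is found by integer bisection on the monotone power curve.
    """
    if or_alt <= 0 or or_alt == 1.0:
        raise ValueError("or_alt must be positive and different from 1")
    if case_control_ratio <= 0:
        raise ValueError("case_control_ratio must be positive")
    if not alpha / 2 < target_power < 1:
        raise ValueError("target_power must lie in (alpha/2, 1)")

    def power_at(cases: int) -> float:
        n_total = int(round(cases * (1 + case_control_ratio)))
        return power_binary(PowerSpec(n_total=n_total, n_cases=cases,
                                      r2=r2, or_alt=or_alt, alpha=alpha))

    lo, hi = 1, 2
    while power_at(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > 10**9:
            raise ValueError("target power unreachable")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def power_table(rows, r2: float = DEFAULT_R2, alpha: float = DEFAULT_ALPHA,
                or_grid: tuple[float, ...] = (1.2, 1.1)):
    """Binary-outcome power at each OR in ``or_grid`` for (name, n_total,
    n_cases) rows; returns a DataFrame with one power column per OR."""
    import pandas as pd

    out = []
    for name, n_total, n_cases in rows:
        entry = {"outcome": name, "n_total": n_total, "n_cases": n_cases}
        for or_alt in or_grid:
            spec = PowerSpec(n_total=n_total, n_cases=n_cases, r2=r2,
                             or_alt=or_alt, alpha=alpha)
            entry[f"power_or_{or_alt:g}"] = power_binary(spec)
        out.append(entry)
    return pd.DataFrame(out)
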