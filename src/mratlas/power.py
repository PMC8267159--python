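"""Instrument-strength and power diagnostics for a binary outcome.

R^2 (exposure variance explained by the instruments) drives both the
F-statistic and the analytic power to detect an assumed causal odds ratio
per SD of exposure. Conventions follow the reproduction targets exactly:

* F uses the single-regressor form ``R^2 (N - 2) / (1 - R^2)`` with N the
  total outcome-study sample size;
* power uses ``Phi( sqrt(N R^2 K(1-K)) |ln OR| - z_{1-alpha/2} )`` with the
  balanced-design convention ``K(1-K) = 0.25`` by default (the observed case
  fraction is available as an option).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats as sps

from .summary_data import SummaryStats

__all__ = [
    "OR_LEVELS",
    "OutcomeMeta",
    "PowerProfile",
    "variance_explained",
    "f_statistic",
    "mr_power_binary",
    "power_profile",
    "power_profile_from_r2",
]

#: The four assumed odds-ratio levels (symmetric with 0.91, 0.83, 0.75, 0.67).
OR_LEVELS = (1.10, 1.20, 1.33, 1.50)

F_WEAK_CUTOFF = 10.0
POWER_CUTOFF = 0.80


@dataclass(frozen=True)
class OutcomeMeta:
    """Case/control composition of a binary outcome GWAS."""

    name: str
    n_cases: int
    n_controls: int

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


@dataclass
class PowerProfile:
    """R^2, F, and power at the assumed OR levels for one trait/outcome pair."""

    trait_name: str
    r_squared: float
    f_stat: float
    n_outcome: int
    k_cases: float
    power_at: dict[float, float] = field(default_factory=dict)

    @property
    def weak_f(self) -> bool:
        return self.f_stat < F_WEAK_CUTOFF

    @property
    def weak_power(self) -> bool:
        return max(self.power_at.values()) < POWER_CUTOFF

    def to_dict(self) -> dict:
        d = {
            "trait": self.trait_name,
            "r_squared": self.r_squared,
            "f_stat": self.f_stat,
            "n_outcome": self.n_outcome,
            "weak_f": self.weak_f,
            "weak_power": self.weak_power,
        }
        for or_level, p in self.power_at.items():
            d[f"power_or_{or_level:g}"] = p
        return d


def variance_explained(stats: SummaryStats) -> float:
    """Sum of ``2 eaf (1 - eaf) beta^2`` over instruments, clipped to [0, 1].

    Assumes per-SD effect sizes (the standardized-trait approximation).
    Raises if any instrument lacks an allele frequency, naming the SNPs.
    """
    missing = [r.variant_id for r in stats.records if r.eaf is None]
    if missing:
        raise ValueError(
            f"trait {stats.trait_name!r}: eaf missing for {missing}; "
            "R^2 cannot be computed"
        )
    r2 = sum(2.0 * r.eaf * (1.0 - r.eaf) * r.beta**2 for r in stats.records)
    return min(1.0, max(0.0, r2))


def f_statistic(r_squared: float, n: int) -> float:
    """Instrument-strength F, ``R^2 (N - 2) / (1 - R^2)``."""
    if not (0.0 <= r_squared < 1.0):
        raise ValueError(f"r_squared {r_squared} outside [0, 1)")
    if n <= 2:
        raise ValueError(f"sample size {n} must exceed 2")
    return r_squared * (n - 2) / (1.0 - r_squared)


def mr_power_binary(
    r_squared: float,
    n_outcome: int,
    or_assumed: float,
    k_cases: float | None = None,
    alpha: float = 0.05,
    balanced: bool = True,
) -> float:
    """Analytic power to detect ``or_assumed`` per SD of exposure.

    With ``balanced=True`` (default) the case-fraction term K(1-K) is fixed
    at 0.25; otherwise it is computed from ``k_cases``. At ``or_assumed = 1``
    (or R^2 = 0) this degrades to the one-sided tail Phi(-z), about 0.025.
    """
    if or_assumed <= 0:
        raise ValueError("or_assumed must be positive")
    if not (0.0 <= r_squared <= 1.0):
        raise ValueError(f"r_squared {r_squared} outside [0, 1]")
    if balanced:
        kvar = 0.25
    else:
        if k_cases is None or not (0.0 < k_cases < 1.0):
            raise ValueError("k_cases in (0, 1) required when balanced=False")
        kvar = k_cases * (1.0 - k_cases)
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    ncp = math.sqrt(n_outcome * r_squared * kvar) * abs(math.log(or_assumed))
    return float(sps.norm.cdf(ncp - z_crit))


def power_profile_from_r2(
    trait_name: str,
    r_squared: float,
    outcome: OutcomeMeta,
    or_levels: tuple[float, ...] = OR_LEVELS,
    alpha: float = 0.05,
    balanced: bool = True,
) -> PowerProfile:
    """Assemble a profile from a known R^2 (e.g. one quoted by the source GWAS)."""
    n = outcome.n_total
    return PowerProfile(
        trait_name=trait_name,
        r_squared=r_squared,
        f_stat=f_statistic(r_squared, n),
        n_outcome=n,
        k_cases=outcome.case_fraction,
        power_at={
            level: mr_power_binary(
                r_squared,
                n,
                level,
                k_cases=outcome.case_fraction,
                alpha=alpha,
                balanced=balanced,
            )
            for level in or_levels
        },
    )


def power_profile(
    stats: SummaryStats,
    outcome: OutcomeMeta,
    or_levels: tuple[float, ...] = OR_LEVELS,
    alpha: float = 0.05,
    balanced: bool = True,
) -> PowerProfile:
    """Assemble a profile computing R^2 from the instruments themselves."""
    return power_profile_from_r2(
        stats.trait_name,
        variance_explained(stats),
        outcome,
        or_levels=or_levels,
        alpha=alpha,
        balanced=balanced,
    )
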