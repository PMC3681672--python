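"""Crypt-based demography of a Barrett's segment under logistic growth.

The Barrett's segment is modeled as a population of crypts (the clonal
proliferative units of the epithelium) growing logistically from a single
founder crypt to ``N_t`` crypts at baseline endoscopy, with carrying
capacity ``K`` set by the physical size of the segment:

    N(t) = K / (1 + (K - 1) * exp(-r * t)),   N(0) = 1,

with intrinsic growth rate ``r = ln(2) / T_r`` where ``T_r`` is the crypt
doubling time in days.  The time from initiation (one crypt) to baseline
(``N_t`` crypts) follows in closed form:

    T_init = (1/r) * ln(N_t * (K - 1) / (K - N_t)).

All rates are per day internally; ``T_init`` is reported in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class LogisticDemography:
    """Logistic crypt-population trajectory of one Barrett's segment.

    Parameters
    ----------
    K : float
        Crypt carrying capacity of the segment (count).
    N_t : float
        Crypt count at baseline endoscopy (count), ``1 <= N_t <= K``.
    T_r : float
        Crypt doubling time in days.
    I_b : float, optional
        Fraction of crypts observed branching (dimensionless), kept for
        provenance when ``T_r`` was derived from it.
    """

    K: float
    N_t: float
    T_r: float
    I_b: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.N_t <= self.K):
            raise ValueError(f"require 1 <= N_t <= K, got N_t={self.N_t}, K={self.K}")
        if self.T_r <= 0:
            raise ValueError("crypt doubling time T_r must be positive")

    @property
    def r(self) -> float:
        """Intrinsic growth rate, 1/day."""
        return math.log(2.0) / self.T_r

    @property
    def T_init(self) -> float:
        """Years from segment initiation (1 crypt) to baseline (N_t crypts)."""
        return initiation_time(self.K, self.N_t, self.T_r)

    def size_at(self, t_days: float) -> float:
        """Crypt count ``N(t)`` at ``t_days`` after initiation (clipped at >= 1)."""
        if t_days <= 0:
            return 1.0
        # guard overflow for very old times
        z = -self.r * t_days
        return self.K / (1.0 + (self.K - 1.0) * math.exp(z))

    def size_years_before_baseline(self, age_years: float) -> float:
        """Crypt count at ``age_years`` before baseline endoscopy.

        Times older than initiation clip to the founder crypt (N = 1).
        """
        t_days = (self.T_init - age_years) * DAYS_PER_YEAR
        return self.size_at(t_days)


def build_demography(
    K: float, N_t: float, T_r: float, *, capacity_margin: float = 0.5, I_b: float | None = None
) -> LogisticDemography:
    """Construct a :class:`LogisticDemography`, validating the crypt counts.

    A baseline exactly at carrying capacity (``N_t == K``) has no finite
    initiation time under the logistic; the baseline count is nudged to
    ``K - capacity_margin`` and a warning is emitted.
    """
    if N_t <= 1:
        raise ValueError("baseline crypt count N_t must exceed 1")
    if N_t > K:
        raise ValueError("baseline crypt count cannot exceed carrying capacity")
    if N_t == K:
        import warnings

        warnings.warn(
            "baseline crypt count is at carrying capacity; using K - "
            f"{capacity_margin} to obtain a finite initiation time",
            stacklevel=2,
        )
        N_t = K - capacity_margin
    return LogisticDemography(K=K, N_t=N_t, T_r=T_r, I_b=I_b)


def initiation_time(K: float, N_t: float, T_r: float) -> float:
    """Years for one crypt to grow logistically to ``N_t`` with capacity ``K``.

    Closed-form inversion of the logistic trajectory with N(0) = 1.
    """
    if N_t <= 1:
        return 0.0
    if N_t >= K:
        raise ValueError("N_t must be below carrying capacity for a finite time")
    r = math.log(2.0) / T_r  # 1/day
    t_days = (1.0 / r) * math.log(N_t * (K - 1.0) / (K - N_t))
    return t_days / DAYS_PER_YEAR


def crypt_doubling_time(I_b: float, branching_visibility: float = 30.0) -> float:
    """Estimate crypt doubling time ``T_r`` (days) from the branching fraction.

    Crypts divide by branching (fission); a branching figure is visible for
    roughly ``branching_visibility`` days of each division cycle, so the
    fraction of crypts caught branching in a histological snapshot is the
    visible fraction of the cycle:  ``T_r = branching_visibility / I_b``.
    This is a deliberately coarse snapshot model — an approximation, not a
    measurement.
    """
    if not 0 < I_b < 1:
        raise ValueError("branching fraction I_b must lie strictly in (0, 1)")
    if branching_visibility <= 0:
        raise ValueError("branching_visibility must be positive (days)")
    return branching_visibility / I_b


def coalescent_hazard_integral(
    demography: LogisticDemography, age_lo: float, age_hi: float, pop_scale: float = 1.0
) -> float:
    """Integral of ``1 / N(t)`` over tree ages (years before baseline).

    ``age`` increases into the past; the integral runs from ``age_lo`` to
    ``age_hi`` (``age_hi >= age_lo``).  Ages beyond initiation clip at
    N = 1.  ``pop_scale`` multiplies N (generation-time/effective-size
    scaling of the crypt count).  Uses the closed-form antiderivative of
    the reciprocal logistic:

        integral of 1/N(s) ds = s/K + (K-1)/(r*K) * (1 - exp(-r*s)) + C

    with s measured in days since initiation.
    """
    if age_hi < age_lo:
        raise ValueError("age_hi must be >= age_lo")
    T_init = demography.T_init
    K, r = demography.K, demography.r

    def anti(s_days: float) -> float:
        # antiderivative of 1/N(s) in days
        return s_days / K + (K - 1.0) / (r * K) * (1.0 - math.exp(-r * s_days))

    # convert ages (years before baseline) to days since initiation
    s_lo = (T_init - age_hi) * DAYS_PER_YEAR  # older age -> earlier s
    s_hi = (T_init - age_lo) * DAYS_PER_YEAR
    total_days = 0.0
    # portion before initiation (s < 0): founder crypt, N = 1
    if s_lo < 0:
        total_days += min(0.0, s_hi) - s_lo
        s_lo = 0.0
    if s_hi > 0:
        total_days += anti(s_hi) - anti(s_lo)
    return total_days / DAYS_PER_YEAR / pop_scale


def population_size_at_age(
    demography: LogisticDemography, age_years: float, pop_scale: float = 1.0
) -> float:
    """Effective size (crypts times ``pop_scale``) at an age before baseline."""
    return demography.size_years_before_baseline(age_years) * pop_scale
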