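"""Years of life lost (YLL) and DALYs averted.

A death at age ``a`` with residual standard life expectancy ``L`` loses

    YLL = integral_0^L [ K C (a+x) e^{-beta(a+x)} + (1-K) ] e^{-r x} dx,

i.e. life-years optionally age-weighted by ``C x e^{-beta x}`` (toggled
by ``K``) and continuously discounted at rate ``r``.  The closed form is

    YLL = K C e^{r a} / (r+beta)^2
          * [ e^{-(r+beta)(L+a)} (-(r+beta)(L+a) - 1)
              - e^{-(r+beta) a} (-(r+beta) a - 1) ]
        + (1-K)/r * (1 - e^{-r L}),

with the analytic limits L (for the second term as r -> 0) and
K C ((L+a)^2 - a^2)/2 (for the first term as r+beta -> 0) taken
exactly rather than by epsilon substitution.

Disability (YLD) is out of scope: DALYs here are YLLs.  Aggregation to
program totals multiplies deaths averted by the per-death YLL rounded
to two decimals, the precision at which per-death values are reported;
pass ``yll_decimals=None`` for full-precision products (the Monte Carlo
engine does).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .errors import DomainError
from .registry import round_half_away

Event = Literal["neonatal", "stillbirth"]


@dataclass(frozen=True)
class SocialValueChoice:
    """The (r, K) social-value choice plus age-weighting constants.

    ``r`` is the annual discount rate; ``K`` in [0, 1] modulates age
    weighting (K=0 disables it, making beta and C irrelevant); ``beta``
    and ``C`` parameterize the standard age-weight ``C x e^{-beta x}``.
    """

    r: float = 0.03
    K: float = 1.0
    beta: float = 0.04
    C: float = 0.1658

    def __post_init__(self) -> None:
        if self.r < 0:
            raise DomainError("discount rate r must be >= 0")
        if not 0.0 <= self.K <= 1.0:
            raise DomainError("age-weighting modulation K must be in [0, 1]")
        if self.beta < 0 or self.C < 0:
            raise DomainError("beta and C must be >= 0")

    @property
    def label(self) -> str:
        return f"[{self.r:g},{self.K:g}]"

    @classmethod
    def discounted_age_weighted(cls) -> "SocialValueChoice":
        return cls(r=0.03, K=1.0)

    @classmethod
    def undiscounted_age_weighted(cls) -> "SocialValueChoice":
        return cls(r=0.0, K=1.0)

    @classmethod
    def undiscounted(cls) -> "SocialValueChoice":
        return cls(r=0.0, K=0.0, beta=0.0, C=0.0)

    @classmethod
    def discounted(cls) -> "SocialValueChoice":
        return cls(r=0.03, K=0.0, beta=0.0, C=0.0)

    @classmethod
    def standard_columns(cls) -> tuple["SocialValueChoice", ...]:
        """The four conventional (r, K) combinations, in report order."""
        return (
            cls.discounted_age_weighted(),
            cls.undiscounted_age_weighted(),
            cls.undiscounted(),
            cls.discounted(),
        )


@dataclass(frozen=True)
class Demography:
    """Ages at death and residual life expectancies, in years."""

    age_at_death: float = 0.0192
    life_expectancy: float = 62.5
    stillbirth_age: float = 0.0
    stillbirth_life_expectancy: float = 62.5

    def __post_init__(self) -> None:
        if self.age_at_death < 0 or self.stillbirth_age < 0:
            raise DomainError("age at death must be >= 0")
        if self.life_expectancy <= 0 or self.stillbirth_life_expectancy <= 0:
            raise DomainError("life expectancy must be > 0")

    def age(self, event: Event) -> float:
        return self.age_at_death if event == "neonatal" else self.stillbirth_age

    def expectancy(self, event: Event) -> float:
        return (self.life_expectancy if event == "neonatal"
                else self.stillbirth_life_expectancy)


@dataclass(frozen=True)
class DalyResult:
    yll_per_death: float
    deaths: float
    dalys: float

    @property
    def dalys_displayed(self) -> int:
        return int(round_half_away(self.dalys))


def _g(x):
    """Stable 1 - (1+x)e^{-x}; series below x = 1e-3."""
    x = np.asarray(x, dtype=float)
    with np.errstate(under="ignore"):
        direct = 1.0 - (1.0 + x) * np.exp(-x)
    series = x**2 / 2.0 - x**3 / 3.0 + x**4 / 8.0
    return np.where(x < 1e-3, series, direct)


def yll_curve(r: float, K: float, beta: float, C: float, a, L):
    """Vectorized closed-form YLL; ``a`` and ``L`` may be arrays.

    The social-value constants are scalars; analytic limits are used
    at r = 0 and at r + beta = 0.
    """
    a = np.asarray(a, dtype=float)
    L = np.asarray(L, dtype=float)
    rb = r + beta
    if K > 0.0:
        if rb > 0.0:
            # bracket rewritten as G(rb(L+a)) - G(rb a) with
            # G(x) = 1 - (1+x) e^{-x} = x^2/2 - x^3/3 + ..., evaluated
            # by series for small x to avoid catastrophic cancellation;
            # below rb(L+a) = 1e-8 the rb -> 0 polynomial limit is
            # exact to O(rb(L+a)) and immune to underflow
            upper = rb * (L + a)
            lower = rb * a
            limit = K * C * np.exp(r * a) * ((L + a) ** 2 - a**2) / 2.0
            with np.errstate(all="ignore"):
                exact = K * C * np.exp(r * a) / rb**2 * (_g(upper) - _g(lower))
            first = np.where(upper < 1e-8, limit, exact)
        else:  # r = beta = 0: plain integral of C x from a to a+L
            first = K * C * ((L + a) ** 2 - a**2) / 2.0
    else:
        first = np.zeros(np.broadcast(a, L).shape)
    if K < 1.0:
        if r > 0.0:
            # (1 - e^{-rL})/r via expm1; the limit L below rL = 1e-8
            # avoids overflow of 1/r at subnormal discount rates
            with np.errstate(all="ignore"):
                exact = -np.expm1(-r * L) / r
            second = (1.0 - K) * np.where(r * L < 1e-8, L, exact)
        else:  # limit (1 - e^{-rL})/r -> L
            second = (1.0 - K) * L
    else:
        second = 0.0
    out = first + second
    if np.any(~np.isfinite(out)) or np.any(out < 0.0):
        raise DomainError("YLL evaluated to a negative or non-finite value")
    return out


def yll_per_death(
    svc: SocialValueChoice, demo: Demography, event: Event = "neonatal"
) -> float:
    """YLL for one death of the given event type under choice ``svc``."""
    return float(
        yll_curve(svc.r, svc.K, svc.beta, svc.C, demo.age(event), demo.expectancy(event))
    )


def dalys_averted(
    deaths: float,
    svc: SocialValueChoice,
    demo: Demography,
    event: Event = "neonatal",
    *,
    yll_decimals: int | None = 2,
) -> DalyResult:
    """DALYs averted by ``deaths`` averted deaths (may be fractional)."""
    if deaths < 0:
        raise DomainError("deaths averted must be >= 0 for DALY aggregation")
    yll = yll_per_death(svc, demo, event)
    if yll_decimals is not None:
        yll = round_half_away(yll, yll_decimals)
    return DalyResult(yll_per_death=yll, deaths=deaths, dalys=deaths * yll)


def combine_dalys(results: Iterable[DalyResult]) -> float:
    """Total DALYs over component results (e.g. neonatal + stillbirth)."""
    results = list(results)
    if not results:
        raise DomainError("combine_dalys needs at least one component")
    return sum(r.dalys for r in results)
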