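"""Delivery-registry data and the steady-state counterfactual.

The evaluation design is quasi-experimental: the hospital's pre-program
(baseline-year) neonatal mortality rate and intrapartum stillbirth rate
are assumed to have persisted unchanged through the program years had
the program not run.  Expected deaths under that steady-state
counterfactual are ``baseline rate x yearly deliveries``; deaths averted
are expected minus observed.  A generic declining-rate counterfactual
(``trend_expected``) is also provided for sensitivity to national
secular trends.

Rates are computed per total delivery (the convention that reproduces
the program's published arithmetic), not per live birth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError

Outcome = Literal["neonatal", "stillbirth"]

REGISTRY_COLUMNS = ("year", "deliveries", "neonatal_deaths", "stillbirths")


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (not banker's rounding)."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass(frozen=True)
class AnnualOutcome:
    """One registry year: deliveries and the death counts observed."""

    year: int
    deliveries: int
    neonatal_deaths: int
    stillbirths: int

    def __post_init__(self) -> None:
        if self.deliveries < 0 or self.neonatal_deaths < 0 or self.stillbirths < 0:
            raise DomainError(f"negative count in registry year {self.year}")
        if self.neonatal_deaths > self.deliveries:
            raise DomainError(
                f"neonatal deaths exceed deliveries in {self.year}")
        if self.stillbirths > self.deliveries:
            raise DomainError(f"stillbirths exceed deliveries in {self.year}")

    def deaths(self, outcome: Outcome) -> int:
        return self.neonatal_deaths if outcome == "neonatal" else self.stillbirths


@dataclass(frozen=True)
class BaselineRates:
    """Baseline-year mortality rates, as fractions per delivery."""

    nmr: float
    sbr: float
    baseline_year: int

    def __post_init__(self) -> None:
        for name, value in (("nmr", self.nmr), ("sbr", self.sbr)):
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{name}={value} outside [0, 1]")

    def rate(self, outcome: Outcome) -> float:
        return self.nmr if outcome == "neonatal" else self.sbr


@dataclass(frozen=True)
class CounterfactualSeries:
    """Per-year expected/observed/averted deaths and their totals.

    The baseline year is included with ``averted = 0`` by construction;
    totals run over the post-baseline years only.  Expected deaths may
    be kept fractional (``rounded=False`` upstream), in which case
    ``averted`` is fractional too.
    """

    outcome: Outcome
    baseline_year: int
    years: tuple[int, ...]
    expected: tuple[float, ...]
    observed: tuple[int, ...]
    averted: tuple[float, ...]

    @property
    def total_expected(self) -> float:
        return sum(e for y, e in zip(self.years, self.expected) if y > self.baseline_year)

    @property
    def total_observed(self) -> int:
        return sum(o for y, o in zip(self.years, self.observed) if y > self.baseline_year)

    @property
    def total_averted(self) -> float:
        return sum(a for y, a in zip(self.years, self.averted) if y > self.baseline_year)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "expected": self.expected,
                "observed": self.observed,
                "averted": self.averted,
            }
        )


def baseline_rate(deaths: int, deliveries: int) -> float:
    """Deaths per delivery, at full floating precision."""
    if deliveries <= 0:
        raise DomainError(f"deliveries must be positive, got {deliveries}")
    if not 0 <= deaths <= deliveries:
        raise DomainError(f"deaths={deaths} outside [0, {deliveries}]")
    return deaths / deliveries


def steady_state_expected(rate: float, deliveries: int, *, rounded: bool = True) -> float:
    """Expected deaths under the steady-state counterfactual.

    ``rate x deliveries``, rounded half away from zero to the nearest
    integer unless ``rounded=False`` (the probabilistic sensitivity
    analysis keeps expected deaths fractional).
    """
    if not 0.0 <= rate <= 1.0:
        raise DomainError(f"rate={rate} outside [0, 1]")
    if deliveries < 0:
        raise DomainError(f"deliveries={deliveries} negative")
    expected = rate * deliveries
    return round_half_away(expected) if rounded else expected


def trend_expected(
    rate: float,
    deliveries: int,
    annual_decline: float,
    years_since_baseline: int,
    *,
    rounded: bool = True,
) -> float:
    """Expected deaths under a declining-rate counterfactual.

    The baseline rate is compounded down by ``annual_decline`` per year
    (e.g. 0.0126 for a 1.26% annualized national decline) before being
    applied to the year's deliveries.
    """
    if not 0.0 <= annual_decline < 1.0:
        raise DomainError(f"annual_decline={annual_decline} outside [0, 1)")
    if years_since_baseline < 0:
        raise DomainError("years_since_baseline must be >= 0")
    declined = rate * (1.0 - annual_decline) ** years_since_baseline
    return steady_state_expected(declined, deliveries, rounded=rounded)


def baseline_rates_from(
    registry: Sequence[AnnualOutcome], baseline_year: int
) -> BaselineRates:
    """Derive the baseline rates from the registry's baseline year."""
    base = next((r for r in registry if r.year == baseline_year), None)
    if base is None:
        raise ConfigurationError(f"baseline year {baseline_year} not in registry")
    return BaselineRates(
        nmr=baseline_rate(base.neonatal_deaths, base.deliveries),
        sbr=baseline_rate(base.stillbirths, base.deliveries),
        baseline_year=baseline_year,
    )


def deaths_averted(
    registry: Sequence[AnnualOutcome],
    rates: BaselineRates,
    outcome: Outcome,
    *,
    rounded: bool = True,
    annual_decline: float = 0.0,
) -> CounterfactualSeries:
    """Counterfactual expected deaths and deaths averted, per year.

    The baseline year contributes ``averted = 0`` by construction.
    Per-year averted values may be negative (observed above expected)
    and propagate to the totals uncensored.  ``annual_decline > 0``
    switches from the steady-state to the declining-rate counterfactual.
    """
    if not any(r.year == rates.baseline_year for r in registry):
        raise ConfigurationError(
            f"baseline year {rates.baseline_year} not in registry")
    rows = sorted(registry, key=lambda r: r.year)
    rate = rates.rate(outcome)
    years, expected, observed, averted = [], [], [], []
    for row in rows:
        obs = row.deaths(outcome)
        if row.year <= rates.baseline_year:
            exp: float = obs
            avert: float = 0.0
        else:
            exp = trend_expected(
                rate, row.deliveries, annual_decline,
                row.year - rates.baseline_year, rounded=rounded)
            avert = exp - obs
        years.append(row.year)
        expected.append(exp)
        observed.append(obs)
        averted.append(avert)
    return CounterfactualSeries(
        outcome=outcome,
        baseline_year=rates.baseline_year,
        years=tuple(years),
        expected=tuple(expected),
        observed=tuple(observed),
        averted=tuple(averted),
    )


def validate_registry(registry: Iterable[AnnualOutcome]) -> list[tuple[str, str]]:
    """Check registry invariants; returns (severity, message) findings.

    Duplicate years are fatal ("error"); gaps in the year sequence are
    reported as warnings.
    """
    findings: list[tuple[str, str]] = []
    years = [r.year for r in registry]
    seen = set()
    for y in years:
        if y in seen:
            findings.append(("error", f"duplicate registry year {y}"))
        seen.add(y)
    ordered = sorted(seen)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt != prev + 1:
            findings.append(
                ("warning", f"non-consecutive registry years {prev} -> {nxt}"))
    return findings


def read_registry(path) -> list[AnnualOutcome]:
    """Read a registry CSV (``year,deliveries,neonatal_deaths,stillbirths``)."""
    frame = pd.read_csv(path)
    missing = set(REGISTRY_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigurationError(f"registry CSV missing columns {sorted(missing)}")
    return [
        AnnualOutcome(
            year=int(row.year),
            deliveries=int(row.deliveries),
            neonatal_deaths=int(row.neonatal_deaths),
            stillbirths=int(row.stillbirths),
        )
        for row in frame.itertuples()
    ]


def write_registry(registry: Sequence[AnnualOutcome], path) -> None:
    registry_to_frame(registry).to_csv(path, index=False)


def registry_to_frame(registry: Sequence[AnnualOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.year, r.deliveries, r.neonatal_deaths, r.stillbirths) for r in registry],
        columns=list(REGISTRY_COLUMNS),
    )
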