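"""Incremental cost-effectiveness ratio and threshold classification.

The ICER compares the program against a no-intervention null:

    ICER = (Cost_program - Cost_null) / (DALY_program - DALY_null),

in US$ per DALY averted.  Two decision rules are provided: the
GDP-based ceiling ratio (ICER below 1x per-capita GDP is "highly
cost-effective", below 3x "cost-effective") and World Bank league-table
dollar cutoffs per country income level.  Thresholds are strict upper
bounds: an ICER exactly at a cutoff takes the less favourable label.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, DomainError, UndefinedIcerError

#: League-table (highly attractive, attractive) cutoffs, US$/DALY.
LEAGUE_CUTOFFS: dict[str, tuple[float, float]] = {
    "low": (25.0, 150.0),
    "middle": (100.0, 500.0),
}


@dataclass(frozen=True)
class IcerResult:
    incremental_cost: float
    incremental_dalys: float
    icer: float


@dataclass(frozen=True)
class ThresholdSet:
    """Decision thresholds: GDP basis and league-table income level."""

    gdp_per_capita: float = 1649.0
    league_income_level: str = "middle"
    league_cutoffs: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise DomainError("gdp_per_capita must be positive")
        if self.league_cutoffs is None:
            if self.league_income_level not in LEAGUE_CUTOFFS:
                raise ConfigurationError(
                    f"unknown income level {self.league_income_level!r}")
            object.__setattr__(
                self, "league_cutoffs", LEAGUE_CUTOFFS[self.league_income_level])
        highly, attractive = self.league_cutoffs
        if not 0 < highly < attractive:
            raise DomainError("league cutoffs must be positive and ordered")


def icer(
    cost_program: float,
    cost_null: float = 0.0,
    dalys_program_averted: float = 0.0,
    dalys_null: float = 0.0,
) -> IcerResult:
    """ICER of the program versus the null (defaults: zero-cost,
    zero-effect null).  A non-positive incremental effect raises
    :class:`UndefinedIcerError` rather than returning a signed ratio.
    """
    d_cost = cost_program - cost_null
    d_dalys = dalys_program_averted - dalys_null
    if d_dalys <= 0:
        raise UndefinedIcerError(
            f"incremental DALYs averted must be positive, got {d_dalys}")
    return IcerResult(
        incremental_cost=d_cost,
        incremental_dalys=d_dalys,
        icer=d_cost / d_dalys,
    )


def classify_gdp(icer_value: float, gdp_per_capita: float) -> str:
    """WHO-CHOICE GDP-based label for an ICER (US$/DALY averted)."""
    if gdp_per_capita <= 0:
        raise DomainError("gdp_per_capita must be positive")
    if icer_value < gdp_per_capita:
        return "highly cost-effective"
    if icer_value < 3.0 * gdp_per_capita:
        return "cost-effective"
    return "not cost-effective"


def classify_league(icer_value: float, income_level: str) -> str:
    """League-table label for an ICER given the country income level."""
    if income_level not in LEAGUE_CUTOFFS:
        raise ConfigurationError(f"unknown income level {income_level!r}")
    highly, attractive = LEAGUE_CUTOFFS[income_level]
    if icer_value < highly:
        return "highly attractive"
    if icer_value < attractive:
        return "attractive"
    return "neither"
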