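"""Program cost ledger and standardization to reference-year US$.

Nominal (as-reported) component costs are standardized by a
multiplicative factor per component: CPI inflation by component class
(all-items for program costs, physician services for valued volunteer
time, medical commodities for donated equipment) and, for items
incurred in local currency, a purchasing-power-parity step folded into
the same factor.  The CPI series values themselves are not shipped;
the packaged defaults are the per-component standardization ratios of
the reference program (each component's 2019-US$ value over its
nominal value), so the published ledger is reproduced exactly without
an external CPI download.  Volunteered professional time is valued at
occupation day rates times days worked.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError
from .registry import round_half_away

ADJUSTMENT_CLASSES = (
    "cpi_all_items",
    "cpi_physician_services",
    "cpi_medical_commodities",
    "ppp_then_cpi",
    "none",
)

#: Day rates (US$/day, 10-hour days) from 2016 U.S. Department of Labor
#: occupational wage estimates.
DEFAULT_DAY_RATES: Mapping[str, float] = {
    "physician_or_qi_specialist": 1100.0,
    "midwife_or_nurse_practitioner": 500.0,
}

#: NICU renovation cost omitted from the reference ledger (US$).
OMITTED_NICU_RENOVATION = 4980.28


@dataclass(frozen=True)
class CostItem:
    """One cost component: nominal amount plus its adjustment class."""

    component: str
    reported_amount: float
    adjustment_class: str = "none"

    def __post_init__(self) -> None:
        if self.reported_amount < 0:
            raise DomainError(
                f"negative reported amount for component {self.component!r}")
        if self.adjustment_class not in ADJUSTMENT_CLASSES:
            raise ConfigurationError(
                f"unknown adjustment class {self.adjustment_class!r} "
                f"(expected one of {ADJUSTMENT_CLASSES})")


@dataclass(frozen=True)
class AdjustmentFactors:
    """Multiplicative standardization factors.

    Factors are looked up by component label first, then by adjustment
    class; the class ``none`` defaults to 1.0.  Component-level entries
    exist because components sharing a CPI class can still standardize
    differently when their spending is spread over different years.
    """

    by_component: Mapping[str, float] = field(default_factory=dict)
    by_class: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.by_component, self.by_class):
            for key, factor in mapping.items():
                if factor <= 0:
                    raise DomainError(f"non-positive factor for {key!r}")

    def factor_for(self, item: CostItem) -> float:
        if item.component in self.by_component:
            return self.by_component[item.component]
        if item.adjustment_class in self.by_class:
            return self.by_class[item.adjustment_class]
        if item.adjustment_class == "none":
            return 1.0
        raise ConfigurationError(
            f"no adjustment factor for component {item.component!r} "
            f"(class {item.adjustment_class!r})")

    @classmethod
    def identity(cls) -> "AdjustmentFactors":
        return cls(by_class={c: 1.0 for c in ADJUSTMENT_CLASSES})


#: Per-component standardization ratios of the reference program
#: (2019-US$ value / nominal value), with class-level fallbacks for
#: ledgers that introduce new components.
DEFAULT_FACTORS = AdjustmentFactors(
    by_component={
        "funder": 1_059_899.06 / 981_577.62,
        "participant": 35_042.51 / 31_938.20,
        "value_time": 449_346.75 / 417_200.00,
        "local_partner": 99_744.44 / 92_229.72,
        "other": 72_943.36 / 67_330.43,
    },
    by_class={
        "cpi_all_items": 1_059_899.06 / 981_577.62,
        "cpi_physician_services": 449_346.75 / 417_200.00,
        "cpi_medical_commodities": 72_943.36 / 67_330.43,
        "ppp_then_cpi": 99_744.44 / 92_229.72,
        "none": 1.0,
    },
)


@dataclass(frozen=True)
class TimeValuation:
    """Days worked and day rate (US$/day) per professional role."""

    roles: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for role, (days, rate) in self.roles.items():
            if days < 0 or rate < 0:
                raise DomainError(f"negative days or rate for role {role!r}")


def adjust_item(item: CostItem, factors: AdjustmentFactors) -> float:
    """Standardized value of one component (nominal x factor)."""
    return item.reported_amount * factors.factor_for(item)


def total_cost(
    ledger: Sequence[CostItem],
    factors: AdjustmentFactors = DEFAULT_FACTORS,
    *,
    rounded: bool = False,
) -> float:
    """Sum of standardized component costs.

    ``rounded=True`` reports to the nearest dollar; arithmetic is
    otherwise kept at full floating precision.
    """
    if not ledger:
        raise ConfigurationError("cost ledger is empty")
    total = sum(adjust_item(item, factors) for item in ledger)
    return round_half_away(total) if rounded else total


def value_time(valuation: TimeValuation) -> float:
    """Monetary value of volunteered professional time (sum of
    days x day rate over roles)."""
    return sum(days * rate for days, rate in valuation.roles.values())


def timeline_totals(
    quarterly_ledger: pd.DataFrame | Sequence[tuple],
) -> tuple[float, float, float]:
    """Column totals of a quarterly (period, operational,
    infrastructure) cost ledger: (operational, infrastructure, grand)."""
    if isinstance(quarterly_ledger, pd.DataFrame):
        frame = quarterly_ledger
    else:
        rows = list(quarterly_ledger)
        if not rows:
            raise ConfigurationError("quarterly ledger is empty")
        frame = pd.DataFrame(
            [(r[-2], r[-1]) for r in rows], columns=["operational", "infrastructure"])
    if len(frame) == 0:
        raise ConfigurationError("quarterly ledger is empty")
    operational = float(frame["operational"].sum())
    infrastructure = float(frame["infrastructure"].fillna(0).sum())
    return operational, infrastructure, operational + infrastructure


def read_cost_ledger(path) -> list[CostItem]:
    """Read a ledger CSV (``component,reported_amount,adjustment_class``)."""
    frame = pd.read_csv(path)
    required = {"component", "reported_amount", "adjustment_class"}
    if not required <= set(frame.columns):
        raise ConfigurationError(
            f"cost ledger CSV missing columns {sorted(required - set(frame.columns))}")
    return [
        CostItem(
            component=str(row.component),
            reported_amount=float(row.reported_amount),
            adjustment_class=str(row.adjustment_class),
        )
        for row in frame.itertuples()
    ]


def read_quarterly_ledger(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"operational", "infrastructure"}
    if not required <= set(frame.columns):
        raise ConfigurationError(
            f"quarterly ledger CSV missing columns {sorted(required - set(frame.columns))}")
    return frame


def ledger_to_frame(
    ledger: Sequence[CostItem], factors: AdjustmentFactors | None = None
) -> pd.DataFrame:
    frame = pd.DataFrame(
        [(i.component, i.reported_amount, i.adjustment_class) for i in ledger],
        columns=["component", "reported_amount", "adjustment_class"],
    )
    if factors is not None:
        frame["adjusted_amount"] = [adjust_item(i, factors) for i in ledger]
    return frame
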