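"""Synthetic registries and cost ledgers with known ground truth.

Annual death counts are drawn binomially at an underlying per-delivery
rate -- the statistical structure the steady-state analysis assumes --
with optional multiplicative intervention effects and a compounding
secular decline.  The generating scenario travels with the data, so
recovery experiments compare pipeline estimates against the
generator's own expectations, never against published values.  The
binomial (rather than Poisson) family is deliberate: deliveries are a
known finite denominator, and deaths <= deliveries holds by
construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .costing import ADJUSTMENT_CLASSES, CostItem
from .errors import DomainError
from .registry import (
    AnnualOutcome,
    BaselineRates,
    baseline_rates_from,
    deaths_averted,
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of a multi-year registry scenario.

    ``years`` counts post-baseline years; ``intervention_effect`` is a
    per-post-baseline-year multiplicative rate reduction (1.0 = no
    effect, 0.7 = 30% rate reduction) applied on top of the secular
    decline.  The baseline year always uses effect 1.0.
    """

    years: int
    deliveries_per_year: int | Sequence[int] = 10_000
    baseline_nmr: float = 0.031
    baseline_sbr: float = 0.012
    intervention_effect: float | Sequence[float] = 1.0
    secular_decline: float = 0.0
    baseline_year: int = 2012
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 1:
            raise DomainError("need at least one post-baseline year")
        for name, rate in (("baseline_nmr", self.baseline_nmr),
                           ("baseline_sbr", self.baseline_sbr)):
            if not 0.0 <= rate <= 1.0:
                raise DomainError(f"{name}={rate} outside [0, 1]")
        if not 0.0 <= self.secular_decline < 1.0:
            raise DomainError("secular_decline must be in [0, 1)")
        for e in self.effects:
            if not 0.0 < e <= 1.0:
                raise DomainError(f"intervention effect {e} outside (0, 1]")
        for n in self.deliveries:
            if n <= 0:
                raise DomainError("deliveries must be positive")

    @property
    def deliveries(self) -> tuple[int, ...]:
        """Per-year deliveries, baseline first (years + 1 entries)."""
        if isinstance(self.deliveries_per_year, (int, np.integer)):
            return (int(self.deliveries_per_year),) * (self.years + 1)
        seq = tuple(int(n) for n in self.deliveries_per_year)
        if len(seq) != self.years + 1:
            raise DomainError(
                f"need {self.years + 1} delivery counts, got {len(seq)}")
        return seq

    @property
    def effects(self) -> tuple[float, ...]:
        """Per-post-baseline-year intervention effects."""
        if isinstance(self.intervention_effect, (int, float)):
            return (float(self.intervention_effect),) * self.years
        seq = tuple(float(e) for e in self.intervention_effect)
        if len(seq) != self.years:
            raise DomainError(f"need {self.years} effects, got {len(seq)}")
        return seq

    def rate(self, outcome: str, t: int) -> float:
        """True per-delivery rate in year ``baseline_year + t``."""
        base = self.baseline_nmr if outcome == "neonatal" else self.baseline_sbr
        effect = 1.0 if t == 0 else self.effects[t - 1]
        return base * (1.0 - self.secular_decline) ** t * effect


@dataclass(frozen=True)
class SyntheticRegistry:
    """Generated annual outcomes plus the generating scenario."""

    outcomes: tuple[AnnualOutcome, ...]
    spec: ScenarioSpec

    def expected_steady_state_averted(self, outcome: str = "neonatal") -> float:
        """Expectation of the steady-state 'averted' estimator.

        E[estimator] = sum_t n_t (p_0 - p_t): the baseline-rate
        estimate is unbiased for p_0 and observed deaths for n_t p_t.
        Positive under a pure secular decline even with no intervention
        -- the steady-state counterfactual's documented optimism.
        """
        spec = self.spec
        return sum(
            spec.deliveries[t] * (spec.rate(outcome, 0) - spec.rate(outcome, t))
            for t in range(1, spec.years + 1))

    def expected_true_averted(self, outcome: str = "neonatal") -> float:
        """Deaths truly averted by the intervention in expectation:
        the no-intervention rate keeps the secular decline but drops
        the intervention effect."""
        spec = self.spec
        base = spec.baseline_nmr if outcome == "neonatal" else spec.baseline_sbr
        return sum(
            spec.deliveries[t]
            * base * (1.0 - spec.secular_decline) ** t
            * (1.0 - spec.effects[t - 1])
            for t in range(1, spec.years + 1))


def generate_registry(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> SyntheticRegistry:
    """Draw one registry: year-t deaths ~ Binomial(deliveries_t, rate_t),
    independently for neonatal deaths and stillbirths."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    outcomes = []
    for t in range(spec.years + 1):
        n = spec.deliveries[t]
        outcomes.append(AnnualOutcome(
            year=spec.baseline_year + t,
            deliveries=n,
            neonatal_deaths=int(rng.binomial(n, spec.rate("neonatal", t))),
            stillbirths=int(rng.binomial(n, spec.rate("stillbirth", t))),
        ))
    return SyntheticRegistry(outcomes=tuple(outcomes), spec=spec)


def generate_cost_ledger(
    total: float, n_components: int, seed: int = 0
) -> list[CostItem]:
    """Random composition of ``total`` over components (cent-exact)."""
    if total <= 0:
        raise DomainError("total must be positive")
    if n_components < 1:
        raise DomainError("need at least one component")
    rng = np.random.default_rng(seed)
    shares = rng.dirichlet(np.ones(n_components))
    amounts = np.round(total * shares, 2)
    amounts[-1] = round(total - float(amounts[:-1].sum()), 2)
    if amounts[-1] < 0:  # rounding pushed the remainder negative
        amounts[amounts.argmax()] += amounts[-1]
        amounts[-1] = 0.0
    classes = rng.choice(ADJUSTMENT_CLASSES, n_components)
    return [
        CostItem(component=f"component_{i + 1}",
                 reported_amount=float(a), adjustment_class=str(c))
        for i, (a, c) in enumerate(zip(amounts, classes))
    ]


@dataclass(frozen=True)
class RecoverySummary:
    """Replicate distribution of the steady-state averted-total
    estimator against the generator's ground truth."""

    outcome: str
    n_replicates: int
    mean_estimate: float
    sd_estimate: float
    expected_steady_state: float
    expected_true_effect: float
    coverage: float
    estimates: tuple[float, ...] = field(repr=False, default=())

    @property
    def bias(self) -> float:
        return self.mean_estimate - self.expected_steady_state

    @property
    def se_mean(self) -> float:
        return self.sd_estimate / np.sqrt(self.n_replicates)


def recovery_experiment(
    spec: ScenarioSpec,
    n_replicates: int,
    seed: int = 0,
    outcome: str = "neonatal",
) -> RecoverySummary:
    """Repeatedly generate a registry and run the steady-state pipeline.

    Reports the replicate mean/SD of the (fractional) averted total,
    its bias against the estimator's own expectation under the
    generator, and the coverage of per-replicate 95% normal intervals
    built from the estimator's plug-in variance (baseline-rate
    estimation error plus binomial noise in the observed deaths).
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_replicates)
    covered = 0
    truth = None
    for i in range(n_replicates):
        synth = generate_registry(spec, rng)
        if truth is None:
            truth = synth.expected_steady_state_averted(outcome)
            true_effect = synth.expected_true_averted(outcome)
        rates = baseline_rates_from(synth.outcomes, spec.baseline_year)
        series = deaths_averted(synth.outcomes, rates, outcome, rounded=False)
        estimates[i] = series.total_averted
        # estimator variance: baseline-rate estimation error scaled by
        # the post-baseline deliveries, plus binomial noise in the
        # observed deaths (plug-in estimates)
        base = next(r for r in synth.outcomes if r.year == spec.baseline_year)
        p0 = rates.rate(outcome)
        post = [r for r in synth.outcomes if r.year > spec.baseline_year]
        n_post = sum(r.deliveries for r in post)
        var = n_post**2 * p0 * (1.0 - p0) / base.deliveries + sum(
            r.deaths(outcome) * (1.0 - r.deaths(outcome) / r.deliveries)
            for r in post)
        if abs(estimates[i] - truth) <= 1.96 * np.sqrt(var):
            covered += 1
    return RecoverySummary(
        outcome=outcome,
        n_replicates=n_replicates,
        mean_estimate=float(estimates.mean()),
        sd_estimate=float(estimates.std(ddof=1)) if n_replicates > 1 else 0.0,
        expected_steady_state=float(truth),
        expected_true_effect=float(true_effect),
        coverage=covered / n_replicates,
        estimates=tuple(estimates),
    )
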