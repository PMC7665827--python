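"""Probabilistic and one-way sensitivity analysis.

All uncertain parameters are varied simultaneously in a Monte Carlo
run: uniform distributions for the demographic assumptions and the
value of professional time, truncated-at-zero normal distributions for
the yearly death counts (observed, and expected under the steady-state
counterfactual).  Within draws expected deaths stay fractional and the
YLL enters at full precision -- rounding is a display convention.
Intervals are central 95% percentile intervals whose endpoints are
order statistics of the draw vector (no normal approximation).

Three standard-error conventions are offered for the count parameters,
selected by ``se_convention``:

``sample``
    the between-year sample standard deviation (ddof=1) of the four
    post-baseline yearly values of the same series (the default;
    "standard error for the sample" of yearly values);
``poisson``
    sqrt(count), the rare-event convention;
``binomial``
    sqrt(n p (1-p)) with the year's deliveries as denominator.

The tornado analysis reports, per parameter, the output at the
parameter's 5th and 95th percentile with all other parameters at their
central values (the bar ends), and a contribution-to-variance computed
from the joint Monte Carlo draws as the squared Spearman rank
correlation between parameter and output, normalized to sum to one
over the parameters (the spreadsheet-add-in convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .costing import CostItem, AdjustmentFactors, DEFAULT_FACTORS, adjust_item
from .daly import Demography, SocialValueChoice, yll_curve
from .errors import ConfigurationError, DomainError
from .registry import AnnualOutcome, BaselineRates, deaths_averted
from . import registry as _registry

DISTRIBUTIONS = ("uniform", "normal", "fixed")
SE_CONVENTIONS = ("sample", "poisson", "binomial")

#: z for the 5th/95th percentile of a normal distribution.
_Z90 = 1.6448536269514722

OUTPUT_NAMES = (
    "averted_neonatal",
    "averted_stillbirth",
    "cost",
    "dalys_discounted_neonatal",
    "dalys_discounted_both",
    "dalys_undiscounted_neonatal",
    "dalys_undiscounted_both",
    "icer_discounted_neonatal",
    "icer_discounted_both",
    "icer_undiscounted_neonatal",
    "icer_undiscounted_both",
)


@dataclass(frozen=True)
class PsaParameter:
    """One uncertain parameter and its sampling distribution."""

    name: str
    distribution: str
    low: float
    mid: float
    high: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.distribution not in DISTRIBUTIONS:
            raise ConfigurationError(
                f"unknown distribution {self.distribution!r} for {self.name!r}")
        if not self.low <= self.mid <= self.high:
            raise DomainError(
                f"{self.name!r}: low <= mid <= high violated "
                f"({self.low}, {self.mid}, {self.high})")
        if self.distribution == "normal" and (self.se is None or self.se < 0):
            raise ConfigurationError(
                f"{self.name!r}: normal distribution needs se >= 0")

    @property
    def degenerate(self) -> bool:
        if self.distribution == "uniform":
            return self.high == self.low
        if self.distribution == "normal":
            return self.se == 0
        return True

    def sample(self, rng: np.random.Generator, n_draws: int) -> np.ndarray:
        if self.distribution == "uniform":
            if self.degenerate:
                return np.full(n_draws, self.mid)
            return rng.uniform(self.low, self.high, n_draws)
        if self.distribution == "normal":
            # truncated at zero: death counts and costs cannot go negative
            return np.clip(rng.normal(self.mid, self.se, n_draws), 0.0, None)
        return np.full(n_draws, self.mid)

    def quantile(self, p: float) -> float:
        """Marginal quantile, used for the one-way tornado sweeps."""
        if self.distribution == "uniform":
            return self.low + p * (self.high - self.low)
        if self.distribution == "normal":
            z = _Z90 if p == 0.95 else (-_Z90 if p == 0.05 else None)
            if z is None:
                raise ConfigurationError(
                    "normal quantiles implemented for p in {0.05, 0.95}")
            return max(self.mid + z * (self.se or 0.0), 0.0)
        return self.mid


@dataclass(frozen=True)
class PsaResult:
    """Draws, base case, percentile intervals and half-widths."""

    draws: pd.DataFrame
    base_case: Mapping[str, float]
    intervals: Mapping[str, tuple[float, float]]
    half_width: Mapping[str, tuple[float, float]]
    undefined_icer_fraction: Mapping[str, float]
    n_draws: int
    seed: int
    se_convention: str
    spec: tuple[PsaParameter, ...]


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar plus the parameter's variance contribution."""

    name: str
    output_at_p05: float
    output_at_p95: float
    contribution_to_variance: float

    @property
    def swing(self) -> float:
        return abs(self.output_at_p95 - self.output_at_p05)


def sample_parameters(
    spec: Sequence[PsaParameter],
    n_draws: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Independent draws per parameter, one column per name."""
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return pd.DataFrame({p.name: p.sample(rng, n_draws) for p in spec})


def _count_se(
    mids: Mapping[int, float],
    deliveries: Mapping[int, int],
    convention: str,
) -> dict[int, float]:
    if convention == "sample":
        sd = float(np.std(list(mids.values()), ddof=1)) if len(mids) > 1 else 0.0
        return {y: sd for y in mids}
    if convention == "poisson":
        return {y: float(np.sqrt(m)) for y, m in mids.items()}
    if convention == "binomial":
        out = {}
        for y, m in mids.items():
            p = m / deliveries[y]
            out[y] = float(np.sqrt(deliveries[y] * p * (1.0 - p)))
        return out
    raise ConfigurationError(f"unknown SE convention {convention!r}")


def default_psa_spec(
    registry: Sequence[AnnualOutcome],
    rates: BaselineRates,
    *,
    demo: Demography | None = None,
    professional_time: float = 449_346.75,
    se_convention: str = "sample",
    age_relative: float = 0.10,
    life_expectancy_relative: float = 0.10,
    professional_time_relative: float = 0.25,
) -> list[PsaParameter]:
    """The standard sensitivity specification for a steady-state run.

    Uniform +/-10% on the age at death and both life expectancies,
    uniform +/-25% on the (standardized) value of professional time,
    and truncated-normal variation of the yearly observed neonatal
    deaths, observed stillbirths and expected (counterfactual) neonatal
    deaths.  Expected stillbirths are carried as fixed parameters, and
    expected-count centers are fractional (unrounded).
    """
    if se_convention not in SE_CONVENTIONS:
        raise ConfigurationError(f"unknown SE convention {se_convention!r}")
    demo = demo or Demography()
    post = sorted((r for r in registry if r.year > rates.baseline_year),
           key=lambda r: r.year)
    if not post:
        raise ConfigurationError("registry has no post-baseline years")
    deliveries = {r.year: r.deliveries for r in post}
    obs_n = {r.year: float(r.neonatal_deaths) for r in post}
    obs_s = {r.year: float(r.stillbirths) for r in post}
    est_n = {r.year: rates.nmr * r.deliveries for r in post}
    est_s = {r.year: rates.sbr * r.deliveries for r in post}

    def uniform(name: str, mid: float, rel: float) -> PsaParameter:
        return PsaParameter(name, "uniform", mid * (1 - rel), mid, mid * (1 + rel))

    spec = [
        uniform("age_at_death", demo.age_at_death, age_relative),
        uniform("life_expectancy", demo.life_expectancy, life_expectancy_relative),
        uniform("stillbirth_life_expectancy",
                demo.stillbirth_life_expectancy, life_expectancy_relative),
        uniform("professional_time", professional_time, professional_time_relative),
    ]
    for prefix, mids in (("obs_neonatal", obs_n), ("est_neonatal", est_n),
                         ("obs_stillbirth", obs_s)):
        ses = _count_se(mids, deliveries, se_convention)
        for year, mid in mids.items():
            spec.append(PsaParameter(
                name=f"{prefix}_{year}", distribution="normal",
                low=max(mid - 1.96 * ses[year], 0.0), mid=mid,
                high=mid + 1.96 * ses[year], se=ses[year]))
    for year, mid in est_s.items():
        spec.append(PsaParameter(f"est_stillbirth_{year}", "fixed", mid, mid, mid))
    return spec


def _fixed_cost(
    ledger: Sequence[CostItem],
    factors: AdjustmentFactors,
    value_time_component: str,
) -> float:
    """Standardized total of all components except the varied one."""
    return sum(adjust_item(i, factors) for i in ledger
               if i.component != value_time_component)


def _model_mids(
    registry: Sequence[AnnualOutcome],
    rates: BaselineRates,
    demo: Demography,
    professional_time: float,
) -> dict[str, float]:
    post = sorted((r for r in registry if r.year > rates.baseline_year),
           key=lambda r: r.year)
    mids: dict[str, float] = {
        "age_at_death": demo.age_at_death,
        "life_expectancy": demo.life_expectancy,
        "stillbirth_life_expectancy": demo.stillbirth_life_expectancy,
        "professional_time": professional_time,
    }
    for r in post:
        mids[f"obs_neonatal_{r.year}"] = float(r.neonatal_deaths)
        mids[f"obs_stillbirth_{r.year}"] = float(r.stillbirths)
        mids[f"est_neonatal_{r.year}"] = rates.nmr * r.deliveries
        mids[f"est_stillbirth_{r.year}"] = rates.sbr * r.deliveries
    return mids


def _evaluate(
    values: Mapping[str, np.ndarray | float],
    svc: SocialValueChoice,
    fixed_cost: float,
    years: Sequence[int],
) -> dict[str, np.ndarray | float]:
    """Map parameter values (scalars or aligned arrays) to the outputs."""
    av_n = sum(values[f"est_neonatal_{y}"] for y in years) \
        - sum(values[f"obs_neonatal_{y}"] for y in years)
    av_s = sum(values[f"est_stillbirth_{y}"] for y in years) \
        - sum(values[f"obs_stillbirth_{y}"] for y in years)
    a = values["age_at_death"]
    life = values["life_expectancy"]
    life_sb = values["stillbirth_life_expectancy"]
    yll_n = yll_curve(svc.r, svc.K, svc.beta, svc.C, a, life)
    yll_s = yll_curve(svc.r, svc.K, svc.beta, svc.C, 0.0, life_sb)
    cost = fixed_cost + values["professional_time"]
    out: dict[str, np.ndarray | float] = {
        "averted_neonatal": av_n,
        "averted_stillbirth": av_s,
        "cost": cost,
        "dalys_discounted_neonatal": av_n * yll_n,
        "dalys_discounted_both": av_n * yll_n + av_s * yll_s,
        "dalys_undiscounted_neonatal": av_n * life,
        "dalys_undiscounted_both": av_n * life + av_s * life_sb,
    }
    for scenario in ("discounted_neonatal", "discounted_both",
                     "undiscounted_neonatal", "undiscounted_both"):
        d = np.asarray(out[f"dalys_{scenario}"], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"icer_{scenario}"] = np.where(d > 0.0, cost / np.where(d > 0, d, 1.0),
                                               np.nan)
    return out


def _order_statistic_interval(arr: np.ndarray) -> tuple[float, float]:
    defined = arr[np.isfinite(arr)]
    lo, hi = np.quantile(defined, [0.025, 0.975], method="closest_observation")
    return float(lo), float(hi)


def run_psa(
    registry: Sequence[AnnualOutcome],
    ledger: Sequence[CostItem],
    *,
    rates: BaselineRates | None = None,
    svc: SocialValueChoice | None = None,
    demo: Demography | None = None,
    factors: AdjustmentFactors = DEFAULT_FACTORS,
    spec: Sequence[PsaParameter] | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    se_convention: str = "sample",
    value_time_component: str = "value_time",
) -> PsaResult:
    """Joint Monte Carlo over the sensitivity specification.

    Per draw the whole pipeline is recomputed: deaths averted
    (fractional expected counts), YLL at the drawn age and life
    expectancy, program cost with the drawn professional-time value,
    DALYs and ICER for the four (discounting x outcome-set) scenarios.
    Draws whose total DALYs averted are not positive are recorded as
    undefined-ICER and excluded from the ICER percentiles, with their
    frequency reported.
    """
    svc = svc or SocialValueChoice.discounted_age_weighted()
    demo = demo or Demography()
    rates = rates or _registry.baseline_rates_from(
        registry, min(r.year for r in registry))
    vt = [i for i in ledger if i.component == value_time_component]
    professional_time = adjust_item(vt[0], factors) if vt else 0.0
    if spec is None:
        spec = default_psa_spec(
            registry, rates, demo=demo, professional_time=professional_time,
            se_convention=se_convention)
    fixed_cost = _fixed_cost(ledger, factors, value_time_component)
    years = sorted(r.year for r in registry if r.year > rates.baseline_year)

    mids = _model_mids(registry, rates, demo, professional_time)
    unknown = [p.name for p in spec if p.name not in mids]
    if unknown:
        raise ConfigurationError(f"spec names not in the model: {unknown}")

    draws = sample_parameters(spec, n_draws, seed)
    values: dict[str, np.ndarray | float] = dict(mids)
    for name in draws.columns:
        values[name] = draws[name].to_numpy()
    outputs = _evaluate(values, svc, fixed_cost, years)
    base = _evaluate(mids, svc, fixed_cost, years)
    base_case = {k: float(np.asarray(v).reshape(-1)[0]) for k, v in base.items()}

    out_frame = draws.copy()
    for name in OUTPUT_NAMES:
        out_frame[name] = np.broadcast_to(
            np.asarray(outputs[name], dtype=float), (n_draws,))

    intervals: dict[str, tuple[float, float]] = {}
    half_width: dict[str, tuple[float, float]] = {}
    undefined: dict[str, float] = {}
    for name in OUTPUT_NAMES:
        arr = out_frame[name].to_numpy()
        if name.startswith("icer_"):
            undefined[name] = float(np.mean(~np.isfinite(arr)))
        lo, hi = _order_statistic_interval(arr)
        intervals[name] = (lo, hi)
        half_width[name] = (base_case[name] - lo, hi - base_case[name])

    return PsaResult(
        draws=out_frame, base_case=base_case, intervals=intervals,
        half_width=half_width, undefined_icer_fraction=undefined,
        n_draws=n_draws, seed=seed, se_convention=se_convention,
        spec=tuple(spec))


def contributions_to_variance(
    result: PsaResult, output: str = "icer_discounted_both"
) -> dict[str, float]:
    """Squared Spearman rank correlation of each parameter with the
    output, normalized to sum to one over the parameters."""
    out = result.draws[output]
    mask = np.isfinite(out.to_numpy())
    out_rank = out[mask].rank()
    rho2: dict[str, float] = {}
    for p in result.spec:
        col = result.draws[p.name][mask]
        if col.nunique() <= 1:
            rho2[p.name] = 0.0
            continue
        rho = np.corrcoef(col.rank(), out_rank)[0, 1]
        rho2[p.name] = float(rho**2)
    total = sum(rho2.values())
    if total == 0.0:
        return rho2
    return {k: v / total for k, v in rho2.items()}


def tornado(
    registry: Sequence[AnnualOutcome],
    ledger: Sequence[CostItem],
    *,
    rates: BaselineRates | None = None,
    svc: SocialValueChoice | None = None,
    demo: Demography | None = None,
    factors: AdjustmentFactors = DEFAULT_FACTORS,
    spec: Sequence[PsaParameter] | None = None,
    output: str = "icer_discounted_both",
    n_draws: int = 10_000,
    seed: int = 0,
    se_convention: str = "sample",
    value_time_component: str = "value_time",
    psa_result: PsaResult | None = None,
) -> list[TornadoEntry]:
    """One-way sweeps plus variance-contribution ranking.

    Bar ends: the output with the parameter at its marginal 5th/95th
    percentile and every other parameter at its central value.
    Contributions come from the joint Monte Carlo draws (reused from
    ``psa_result`` when given).  Entries are sorted by descending
    contribution; the full list is returned -- report layers apply the
    >= 4% display cutoff.
    """
    if psa_result is None:
        psa_result = run_psa(
            registry, ledger, rates=rates, svc=svc, demo=demo, factors=factors,
            spec=spec, n_draws=n_draws, seed=seed, se_convention=se_convention,
            value_time_component=value_time_component)
    spec = list(psa_result.spec)
    svc = svc or SocialValueChoice.discounted_age_weighted()
    demo = demo or Demography()
    rates = rates or _registry.baseline_rates_from(
        registry, min(r.year for r in registry))
    vt = [i for i in ledger if i.component == value_time_component]
    professional_time = adjust_item(vt[0], factors) if vt else 0.0
    fixed_cost = _fixed_cost(ledger, factors, value_time_component)
    years = sorted(r.year for r in registry if r.year > rates.baseline_year)
    mids = _model_mids(registry, rates, demo, professional_time)

    contrib = contributions_to_variance(psa_result, output)
    entries = []
    for p in spec:
        lo_point = dict(mids)
        hi_point = dict(mids)
        lo_point[p.name] = p.quantile(0.05)
        hi_point[p.name] = p.quantile(0.95)
        lo_out = float(np.asarray(_evaluate(lo_point, svc, fixed_cost, years)[output]))
        hi_out = float(np.asarray(_evaluate(hi_point, svc, fixed_cost, years)[output]))
        entries.append(TornadoEntry(
            name=p.name, output_at_p05=lo_out, output_at_p95=hi_out,
            contribution_to_variance=contrib[p.name]))
    entries.sort(key=lambda e: e.contribution_to_variance, reverse=True)
    return entries


def tornado_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.name, e.output_at_p05, e.output_at_p95, e.contribution_to_variance)
         for e in entries],
        columns=["parameter", "output_at_p05", "output_at_p95",
                 "contribution_to_variance"],
    )


def plot_tornado(entries: Sequence[TornadoEntry], base_value: float, path) -> None:
    """Horizontal-bar tornado chart (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.swing)
    names = [e.name for e in entries]
    lows = np.array([min(e.output_at_p05, e.output_at_p95) for e in entries])
    highs = np.array([max(e.output_at_p05, e.output_at_p95) for e in entries])
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    ax.barh(names, highs - lows, left=lows, color="steelblue")
    ax.axvline(base_value, color="black", lw=1)
    ax.set_xlabel("output at parameter's 5th-95th percentile")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_psa_spec(path) -> list[PsaParameter]:
    """Read a spec CSV (``name,distribution,low,mid,high,se``)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"name", "distribution", "low", "mid", "high"}
    if not required <= set(frame.columns):
        raise ConfigurationError(
            f"PSA spec CSV missing columns {sorted(required - set(frame.columns))}")
    out = []
    for row in frame.itertuples():
        se = getattr(row, "se", None)
        out.append(PsaParameter(
            name=str(row.name), distribution=str(row.distribution),
            low=float(row.low), mid=float(row.mid), high=float(row.high),
            se=None if se is None or pd.isna(se) else float(se)))
    return out


def write_psa_spec(spec: Sequence[PsaParameter], path) -> None:
    pd.DataFrame(
        [(p.name, p.distribution, p.low, p.mid, p.high, p.se) for p in spec],
        columns=["name", "distribution", "low", "mid", "high", "se"],
    ).to_csv(path, index=False)
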