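"""End-to-end analysis driver: configuration, validation, reporting.

``run_analysis`` chains the stages -- registry counterfactual, YLL
table under the four social-value choices, cost standardization, ICER
with threshold classification, probabilistic sensitivity analysis and
tornado ranking -- and collects every table a report needs.  All
randomness flows from the single configured seed, so regenerating a
report from the same inputs is byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib.resources import files
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cea, costing, daly, registry, uncertainty
from .errors import ConfigurationError

log = logging.getLogger("neocea")

_DATA = files("neocea") / "data"

SCENARIOS = (
    ("discounted_neonatal", "Discounted, neonatal deaths"),
    ("discounted_both", "Discounted, neonatal deaths and stillbirths"),
    ("undiscounted_neonatal", "Undiscounted, neonatal deaths"),
    ("undiscounted_both", "Undiscounted, neonatal deaths and stillbirths"),
)


def packaged_path(name: str):
    """Path-like handle to a packaged reference data file."""
    return _DATA / name


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one analysis run needs; see ``data/config.yaml``."""

    registry_path: object = None      # None -> packaged reference registry
    cost_ledger_path: object = None
    quarterly_path: object = None
    psa_spec_path: object = None      # None -> derived from the registry
    baseline_year: int = 2012
    demography: daly.Demography = field(default_factory=daly.Demography)
    social_value: daly.SocialValueChoice = field(
        default_factory=daly.SocialValueChoice.discounted_age_weighted)
    thresholds: cea.ThresholdSet = field(default_factory=cea.ThresholdSet)
    factors: costing.AdjustmentFactors = costing.DEFAULT_FACTORS
    include_nicu_renovation: bool = False
    n_draws: int = 10_000
    seed: int = 2016
    se_convention: str = "sample"
    min_contribution: float = 0.04
    output_dir: object = None

    @classmethod
    def default(cls) -> "AnalysisConfig":
        return cls.from_yaml(packaged_path("config.yaml"))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        demo_raw = raw.get("demography", {})
        svc_raw = raw.get("social_value", {})
        thresh_raw = raw.get("thresholds", {})
        psa_raw = raw.get("psa", {})
        cfg = cls(
            baseline_year=int(raw.get("baseline_year", 2012)),
            demography=daly.Demography(
                age_at_death=demo_raw.get("age_at_death", 0.0192),
                life_expectancy=demo_raw.get("life_expectancy", 62.5),
                stillbirth_age=demo_raw.get("stillbirth_age", 0.0),
                stillbirth_life_expectancy=demo_raw.get(
                    "stillbirth_life_expectancy", 62.5),
            ),
            social_value=daly.SocialValueChoice(
                r=svc_raw.get("discount_rate", 0.03),
                K=svc_raw.get("age_weight_K", 1.0),
                beta=svc_raw.get("age_weight_beta", 0.04),
                C=svc_raw.get("age_weight_C", 0.1658),
            ),
            thresholds=cea.ThresholdSet(
                gdp_per_capita=thresh_raw.get("gdp_per_capita", 1649),
                league_income_level=thresh_raw.get("league_income_level", "middle"),
            ),
            include_nicu_renovation=raw.get("costing", {}).get(
                "include_nicu_renovation", False),
            n_draws=int(psa_raw.get("n_draws", 10_000)),
            seed=int(psa_raw.get("seed", 2016)),
            se_convention=psa_raw.get("se_convention", "sample"),
            min_contribution=raw.get("tornado", {}).get("min_contribution", 0.04),
            registry_path=raw.get("registry_path"),
            cost_ledger_path=raw.get("cost_ledger_path"),
            quarterly_path=raw.get("quarterly_path"),
            psa_spec_path=raw.get("psa_spec_path"),
        )
        return replace(cfg, **overrides) if overrides else cfg

    # --- input loading -------------------------------------------------
    def load_registry(self) -> list[registry.AnnualOutcome]:
        return registry.read_registry(self.registry_path or packaged_path("registry.csv"))

    def load_ledger(self) -> list[costing.CostItem]:
        ledger = costing.read_cost_ledger(
            self.cost_ledger_path or packaged_path("cost_ledger.csv"))
        if self.include_nicu_renovation:
            ledger.append(costing.CostItem(
                "nicu_renovation", costing.OMITTED_NICU_RENOVATION,
                "cpi_medical_commodities"))
        return ledger

    def load_quarterly(self) -> pd.DataFrame:
        return costing.read_quarterly_ledger(
            self.quarterly_path or packaged_path("quarterly_costs.csv"))

    def load_psa_spec(self):
        if self.psa_spec_path is None:
            return None
        return uncertainty.read_psa_spec(self.psa_spec_path)


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[tuple[str, str], ...]

    @property
    def fatal(self) -> bool:
        return any(sev == "error" for sev, _ in self.findings)

    def __str__(self) -> str:
        if not self.findings:
            return "inputs valid"
        return "\n".join(f"{sev.upper()}: {msg}" for sev, msg in self.findings)


def validate_inputs(config: AnalysisConfig) -> ValidationReport:
    """Check registry, ledger and PSA-spec invariants before a run."""
    findings: list[tuple[str, str]] = []
    try:
        reg = config.load_registry()
        findings.extend(registry.validate_registry(reg))
        if not any(r.year == config.baseline_year for r in reg):
            findings.append(
                ("error", f"baseline year {config.baseline_year} not in registry"))
        elif not any(r.year > config.baseline_year for r in reg):
            findings.append(("error", "no post-baseline years in registry"))
    except Exception as exc:  # noqa: BLE001 - collected into the report
        findings.append(("error", f"registry: {exc}"))
    try:
        ledger = config.load_ledger()
        for item in ledger:
            config.factors.factor_for(item)
    except Exception as exc:  # noqa: BLE001
        findings.append(("error", f"cost ledger: {exc}"))
    try:
        config.load_psa_spec()
    except Exception as exc:  # noqa: BLE001
        findings.append(("error", f"PSA spec: {exc}"))
    if config.se_convention not in uncertainty.SE_CONVENTIONS:
        findings.append(
            ("error", f"unknown SE convention {config.se_convention!r}"))
    return ValidationReport(tuple(findings))


@dataclass(frozen=True)
class AnalysisReport:
    """Every table of one end-to-end run, plus provenance."""

    config: AnalysisConfig
    counterfactual: pd.DataFrame
    yll_table: pd.DataFrame
    cost_summary: pd.DataFrame
    quarterly_totals: tuple[float, float, float]
    base_case: pd.DataFrame
    classifications: Mapping[str, str]
    tornado_entries: tuple[uncertainty.TornadoEntry, ...]
    psa: uncertainty.PsaResult

    @property
    def tornado_reported(self) -> tuple[uncertainty.TornadoEntry, ...]:
        """Entries above the configured display cutoff."""
        return tuple(e for e in self.tornado_entries
                     if e.contribution_to_variance >= self.config.min_contribution)

    def headline(self) -> dict[str, float | str]:
        row = self.base_case.set_index("scenario").loc["discounted_both"]
        return {
            "neonatal_deaths_averted": int(
                self.counterfactual.query(
                    "outcome == 'neonatal'")["averted"].sum()),
            "stillbirths_averted": int(
                self.counterfactual.query(
                    "outcome == 'stillbirth'")["averted"].sum()),
            "total_cost_usd": float(registry.round_half_away(
                self.cost_summary["adjusted_amount"].sum())),
            "dalys_averted": float(row["dalys"]),
            "icer_usd_per_daly": float(row["icer"]),
            "gdp_classification": self.classifications["gdp"],
            "league_classification": self.classifications["league"],
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counterfactual.to_csv(outdir / "counterfactual.csv", index=False)
        self.yll_table.to_csv(outdir / "yll_table.csv", index=False)
        self.cost_summary.to_csv(outdir / "cost_summary.csv", index=False)
        self.base_case.to_csv(outdir / "base_case.csv", index=False)
        uncertainty.tornado_to_frame(self.tornado_entries).to_csv(
            outdir / "tornado.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.headline(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _counterfactual_frame(reg, rates) -> pd.DataFrame:
    frames = []
    for outcome in ("neonatal", "stillbirth"):
        series = registry.deaths_averted(reg, rates, outcome)
        frame = series.to_frame()
        frame.insert(0, "outcome", outcome)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _yll_frame(demo: daly.Demography) -> pd.DataFrame:
    rows = []
    for svc in daly.SocialValueChoice.standard_columns():
        rows.append({
            "choice": svc.label, "r": svc.r, "K": svc.K,
            "beta": svc.beta, "C": svc.C,
            "yll_neonatal": round(daly.yll_per_death(svc, demo), 2),
            "yll_stillbirth": round(daly.yll_per_death(svc, demo, "stillbirth"), 2),
        })
    return pd.DataFrame(rows)


def run_analysis(config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the whole analysis under ``config`` (default: the packaged
    reference program) and return the collected report."""
    config = config or AnalysisConfig.default()
    report = validate_inputs(config)
    if report.fatal:
        raise ConfigurationError(f"invalid inputs:\n{report}")
    for sev, msg in report.findings:
        log.warning("%s: %s", sev, msg)

    log.info("stage registry: loading inputs and computing counterfactual")
    reg = config.load_registry()
    rates = registry.baseline_rates_from(reg, config.baseline_year)
    counterfactual = _counterfactual_frame(reg, rates)

    log.info("stage daly: YLL table under the standard social-value choices")
    demo = config.demography
    yll_table = _yll_frame(demo)

    log.info("stage costing: standardizing the cost ledger")
    ledger = config.load_ledger()
    cost_summary = costing.ledger_to_frame(ledger, config.factors)
    total_cost = costing.total_cost(ledger, config.factors)
    quarterly = costing.timeline_totals(config.load_quarterly())

    log.info("stage cea: ICER and threshold classification")
    averted = {
        o: registry.deaths_averted(reg, rates, o).total_averted
        for o in ("neonatal", "stillbirth")
    }
    svc_disc = config.social_value
    svc_undisc = daly.SocialValueChoice.undiscounted()
    dalys = {
        "discounted_neonatal": daly.dalys_averted(
            averted["neonatal"], svc_disc, demo).dalys,
        "discounted_both": daly.combine_dalys([
            daly.dalys_averted(averted["neonatal"], svc_disc, demo),
            daly.dalys_averted(averted["stillbirth"], svc_disc, demo, "stillbirth"),
        ]),
        "undiscounted_neonatal": daly.dalys_averted(
            averted["neonatal"], svc_undisc, demo).dalys,
        "undiscounted_both": daly.combine_dalys([
            daly.dalys_averted(averted["neonatal"], svc_undisc, demo),
            daly.dalys_averted(averted["stillbirth"], svc_undisc, demo, "stillbirth"),
        ]),
    }
    log.info("stage uncertainty: %d Monte Carlo draws (seed %d, SE=%s)",
             config.n_draws, config.seed, config.se_convention)
    psa = uncertainty.run_psa(
        reg, ledger, rates=rates, svc=svc_disc, demo=demo, factors=config.factors,
        spec=config.load_psa_spec(), n_draws=config.n_draws, seed=config.seed,
        se_convention=config.se_convention)
    entries = uncertainty.tornado(reg, ledger, rates=rates, svc=svc_disc, demo=demo,
                                  factors=config.factors, psa_result=psa)

    rows = []
    for scenario, label in SCENARIOS:
        d = dalys[scenario]
        result = cea.icer(total_cost, 0.0, d, 0.0)
        d_lo, d_hi = psa.intervals[f"dalys_{scenario}"]
        i_lo, i_hi = psa.intervals[f"icer_{scenario}"]
        rows.append({
            "scenario": scenario, "label": label,
            "dalys": registry.round_half_away(d),
            "dalys_lo": d_lo, "dalys_hi": d_hi,
            "icer": round(result.icer, 2),
            "icer_lo": i_lo, "icer_hi": i_hi,
        })
    base_case = pd.DataFrame(rows)

    primary_icer = cea.icer(total_cost, 0.0, dalys["discounted_both"], 0.0).icer
    classifications = {
        "gdp": cea.classify_gdp(primary_icer, config.thresholds.gdp_per_capita),
        "league": cea.classify_league(
            primary_icer, config.thresholds.league_income_level),
    }
    return AnalysisReport(
        config=config, counterfactual=counterfactual, yll_table=yll_table,
        cost_summary=cost_summary, quarterly_totals=quarterly,
        base_case=base_case, classifications=classifications,
        tornado_entries=tuple(entries), psa=psa)
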