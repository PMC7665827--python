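"""Monte Carlo sensitivity machinery: sampling, intervals, tornado."""
import numpy as np
import pandas as pd
import pytest

from neocea import (
    ConfigurationError,
    DomainError,
    PsaParameter,
    contributions_to_variance,
    default_psa_spec,
    run_psa,
    sample_parameters,
    tornado,
)
from neocea.daly import Demography, SocialValueChoice, yll_curve
from neocea.registry import deaths_averted
from neocea.uncertainty import (
    PsaResult,
    read_psa_spec,
    tornado_to_frame,
    write_psa_spec,
)


class TestSampleParameters:
    def test_uniform_mean(self):
        spec = [PsaParameter("L", "uniform", 56.25, 62.5, 68.75)]
        draws = sample_parameters(spec, 50_000, seed=1)["L"]
        assert draws.mean() == pytest.approx(62.5, rel=0.005)
        assert draws.between(56.25, 68.75).all()

    def test_fixed_repeats_mid(self):
        spec = [PsaParameter("k", "fixed", 2.0, 2.0, 2.0)]
        assert (sample_parameters(spec, 100, seed=0)["k"] == 2.0).all()

    def test_normal_coverage_of_printed_bounds(self):
        """Normal draws with bounds mid +/- 1.96 SE cover ~95%."""
        se = np.sqrt(208)
        spec = [PsaParameter("deaths", "normal", 208 - 1.96 * se, 208,
                             208 + 1.96 * se, se=se)]
        draws = sample_parameters(spec, 100_000, seed=3)["deaths"]
        inside = draws.between(208 - 1.96 * se, 208 + 1.96 * se).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_normal_truncated_at_zero(self):
        spec = [PsaParameter("deaths", "normal", 0, 1.0, 10, se=5.0)]
        assert (sample_parameters(spec, 10_000, seed=4)["deaths"] >= 0).all()

    def test_seed_reproducibility(self):
        spec = [PsaParameter("x", "uniform", 0, 1, 2)]
        a = sample_parameters(spec, 100, seed=9)
        b = sample_parameters(spec, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            PsaParameter("x", "triangular", 0, 1, 2)

    def test_disordered_bounds_rejected(self):
        with pytest.raises(DomainError):
            PsaParameter("x", "uniform", 2, 1, 0)


class TestDefaultSpec:
    def test_families_present(self, reference_registry, rates):
        spec = default_psa_spec(reference_registry, rates)
        names = {p.name for p in spec}
        for year in (2013, 2014, 2015, 2016):
            assert {f"obs_neonatal_{year}", f"est_neonatal_{year}",
                    f"obs_stillbirth_{year}", f"est_stillbirth_{year}"} <= names
        assert {"age_at_death", "life_expectancy",
                "stillbirth_life_expectancy", "professional_time"} <= names

    def test_expected_counts_stay_fractional(self, reference_registry, rates):
        spec = {p.name: p for p in default_psa_spec(reference_registry, rates)}
        assert spec["est_neonatal_2013"].mid == pytest.approx(353 / 11338 * 7549)

    def test_sample_se_is_between_year_sd(self, reference_registry, rates):
        spec = {p.name: p for p in default_psa_spec(
            reference_registry, rates, se_convention="sample")}
        observed = [179, 165, 208, 204]
        assert spec["obs_neonatal_2015"].se == \
            pytest.approx(np.std(observed, ddof=1))

    def test_poisson_se_is_sqrt_count(self, reference_registry, rates):
        spec = {p.name: p for p in default_psa_spec(
            reference_registry, rates, se_convention="poisson")}
        assert spec["obs_neonatal_2015"].se == pytest.approx(np.sqrt(208))

    def test_estimated_stillbirths_fixed(self, reference_registry, rates):
        spec = {p.name: p for p in default_psa_spec(reference_registry, rates)}
        assert spec["est_stillbirth_2014"].distribution == "fixed"

    def test_csv_roundtrip(self, reference_registry, rates, tmp_path):
        spec = default_psa_spec(reference_registry, rates)
        path = tmp_path / "spec.csv"
        write_psa_spec(spec, path)
        assert read_psa_spec(path) == spec


def degenerate_spec(reference_registry, rates):
    spec = default_psa_spec(reference_registry, rates)
    out = []
    for p in spec:
        if p.distribution == "normal":
            out.append(PsaParameter(p.name, "normal", p.mid, p.mid, p.mid, se=0.0))
        else:
            out.append(PsaParameter(p.name, p.distribution, p.mid, p.mid, p.mid,
                                    se=p.se))
    return out


class TestRunPsa:
    def test_seed_determinism_is_bitwise(self, reference_registry, reference_ledger):
        a = run_psa(reference_registry, reference_ledger, n_draws=500, seed=11)
        b = run_psa(reference_registry, reference_ledger, n_draws=500, seed=11)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        assert a.intervals == b.intervals
        assert a.base_case == b.base_case

    def test_degenerate_spec_collapses_to_base_case(
            self, reference_registry, reference_ledger, rates, demo):
        """Zero-width distributions reproduce the deterministic
        pipeline (fractional expected deaths, full-precision YLL)
        exactly."""
        result = run_psa(reference_registry, reference_ledger,
                         spec=degenerate_spec(reference_registry, rates),
                         n_draws=200, seed=5)
        svc = SocialValueChoice.discounted_age_weighted()
        averted_n = deaths_averted(
            reference_registry, rates, "neonatal", rounded=False).total_averted
        averted_s = deaths_averted(
            reference_registry, rates, "stillbirth", rounded=False).total_averted
        expected = averted_n * float(yll_curve(
            svc.r, svc.K, svc.beta, svc.C, demo.age_at_death, demo.life_expectancy)) \
            + averted_s * float(yll_curve(
                svc.r, svc.K, svc.beta, svc.C, 0.0, demo.stillbirth_life_expectancy))
        lo, hi = result.intervals["dalys_discounted_both"]
        assert lo == hi == result.base_case["dalys_discounted_both"] == \
            pytest.approx(expected, rel=1e-12)

    def test_interval_endpoints_are_order_statistics(self, psa_sample):
        for name in ("dalys_discounted_both", "icer_discounted_both"):
            draws = psa_sample.draws[name].to_numpy()
            lo, hi = psa_sample.intervals[name]
            assert lo in draws and hi in draws
            assert lo <= psa_sample.base_case[name] <= hi

    def test_undefined_icer_draws_are_excluded_and_counted(
            self, reference_registry, reference_ledger, rates):
        """Forcing observed deaths far above expectation makes some
        draws yield non-positive DALYs averted; those draws are
        flagged, not folded into the percentiles."""
        spec = degenerate_spec(reference_registry, rates)
        spec = [PsaParameter(p.name, "normal", 0, p.mid, p.mid * 3, se=p.mid)
                if p.name.startswith("obs_neonatal") else p for p in spec]
        result = run_psa(reference_registry, reference_ledger, spec=spec,
                         n_draws=4000, seed=6)
        frac = result.undefined_icer_fraction["icer_discounted_neonatal"]
        assert 0 < frac < 1
        assert np.isfinite(result.intervals["icer_discounted_neonatal"]).all()

    def test_unknown_parameter_name_rejected(
            self, reference_registry, reference_ledger):
        with pytest.raises(ConfigurationError):
            run_psa(reference_registry, reference_ledger,
                    spec=[PsaParameter("gremlin", "fixed", 1, 1, 1)],
                    n_draws=10, seed=0)


class TestTornado:
    def test_single_varying_parameter_takes_all_variance(
            self, reference_registry, reference_ledger, rates):
        spec = degenerate_spec(reference_registry, rates)
        spec = [PsaParameter("life_expectancy", "uniform", 56.25, 62.5, 68.75)
                if p.name == "life_expectancy" else p for p in spec]
        entries = tornado(reference_registry, reference_ledger, spec=spec,
                          n_draws=2000, seed=7)
        top = entries[0]
        assert top.name == "life_expectancy"
        assert top.contribution_to_variance == pytest.approx(1.0)

    def test_symmetric_parameters_split_variance_evenly(
            self, reference_registry, reference_ledger, rates):
        """Two parameters with identical distributions and symmetric
        effects on the output contribute ~50% each."""
        spec = degenerate_spec(reference_registry, rates)
        spec = [PsaParameter(p.name, "uniform", p.mid - 50, p.mid, p.mid + 50)
                if p.name in ("obs_neonatal_2013", "obs_neonatal_2014") else p
                for p in spec]
        entries = {e.name: e for e in tornado(
            reference_registry, reference_ledger, spec=spec,
            n_draws=8000, seed=8)}
        assert entries["obs_neonatal_2013"].contribution_to_variance == \
            pytest.approx(0.5, abs=0.05)
        assert entries["obs_neonatal_2014"].contribution_to_variance == \
            pytest.approx(0.5, abs=0.05)

    def test_contributions_normalized(self, psa_sample):
        contrib = contributions_to_variance(psa_sample)
        assert sum(contrib.values()) == pytest.approx(1.0)
        assert all(v >= 0 for v in contrib.values())

    def test_rank_correlation_invariant_to_monotone_rescaling(self, psa_sample):
        """Cubing a positive parameter (a monotone map) leaves its
        Spearman-based contribution unchanged."""
        contrib = contributions_to_variance(psa_sample)
        rescaled_draws = psa_sample.draws.copy()
        rescaled_draws["life_expectancy"] = rescaled_draws["life_expectancy"] ** 3
        rescaled = PsaResult(
            draws=rescaled_draws, base_case=psa_sample.base_case,
            intervals=psa_sample.intervals, half_width=psa_sample.half_width,
            undefined_icer_fraction=psa_sample.undefined_icer_fraction,
            n_draws=psa_sample.n_draws, seed=psa_sample.seed,
            se_convention=psa_sample.se_convention, spec=psa_sample.spec)
        contrib_rescaled = contributions_to_variance(rescaled)
        assert contrib_rescaled["life_expectancy"] == \
            pytest.approx(contrib["life_expectancy"], rel=1e-9)

    def test_sweep_ends_bracket_base_case(
            self, reference_registry, reference_ledger, psa_sample):
        entries = tornado(reference_registry, reference_ledger,
                          psa_result=psa_sample)
        base = psa_sample.base_case["icer_discounted_both"]
        frame = tornado_to_frame(entries)
        varying = frame[frame.contribution_to_variance > 0]
        assert ((varying.output_at_p05 - base)
                * (varying.output_at_p95 - base) <= 0).all()
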