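"""Steady-state counterfactual arithmetic on the delivery registry."""
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neocea import (
    AnnualOutcome,
    BaselineRates,
    ConfigurationError,
    DomainError,
    baseline_rate,
    baseline_rates_from,
    deaths_averted,
    read_registry,
    steady_state_expected,
    trend_expected,
)
from neocea.registry import (
    registry_to_frame,
    round_half_away,
    validate_registry,
    write_registry,
)


class TestBaselineRate:
    @pytest.mark.parametrize(
        "deaths, deliveries, expected",
        [
            (353, 11338, 353 / 11338),  # prints as the 3.11% NMR
            (135, 11338, 135 / 11338),  # prints as 11.91 per 1,000
            (0, 1000, 0.0),
        ],
    )
    def test_full_precision_fraction(self, deaths, deliveries, expected):
        assert baseline_rate(deaths, deliveries) == pytest.approx(expected)

    def test_printed_percent(self):
        assert round(100 * baseline_rate(353, 11338), 2) == 3.11

    @pytest.mark.parametrize("deaths, deliveries", [(1, 0), (1, -5), (-1, 10), (11, 10)])
    def test_domain_errors(self, deaths, deliveries):
        with pytest.raises(DomainError):
            baseline_rate(deaths, deliveries)


class TestSteadyStateExpected:
    @pytest.mark.parametrize(
        "rate, deliveries, expected",
        [
            (353 / 11338, 7549, 235),
            (353 / 11338, 9672, 301),
            (353 / 11338, 8807, 274),
            (353 / 11338, 8129, 253),
            (135 / 11338, 7549, 90),
            (135 / 11338, 9672, 115),
            (135 / 11338, 8807, 105),
            (135 / 11338, 8129, 97),
            (0.5, 0, 0),
        ],
    )
    def test_reference_cells(self, rate, deliveries, expected):
        assert steady_state_expected(rate, deliveries) == expected

    def test_rounds_half_away_from_zero(self):
        assert steady_state_expected(0.0235, 1000) == 24  # 23.5 -> 24
        assert round_half_away(-2.5) == -3

    def test_unrounded_option(self):
        assert steady_state_expected(353 / 11338, 7549, rounded=False) == \
            pytest.approx(353 / 11338 * 7549)

    def test_rate_outside_unit_interval(self):
        with pytest.raises(DomainError):
            steady_state_expected(1.2, 100)


class TestTrendExpected:
    def test_zero_decline_equals_steady_state(self):
        assert trend_expected(353 / 11338, 7549, 0.0, 3) == \
            steady_state_expected(353 / 11338, 7549)

    def test_national_decline_example(self):
        # 235.03 x 0.9874 = 232.1 -> 232
        assert trend_expected(353 / 11338, 7549, 0.0126, 1) == 232

    def test_compounding(self):
        assert trend_expected(0.1, 1000, 0.5, 2) == 25

    def test_negative_years_rejected(self):
        with pytest.raises(DomainError):
            trend_expected(0.1, 1000, 0.1, -1)


class TestDeathsAverted:
    def test_reproduces_reference_neonatal_series(self, reference_registry, rates):
        series = deaths_averted(reference_registry, rates, "neonatal")
        assert series.expected == (353, 235, 301, 274, 253)
        assert series.averted == (0, 56, 136, 66, 49)
        assert series.total_averted == 307

    def test_reproduces_reference_stillbirth_series(self, reference_registry, rates):
        series = deaths_averted(reference_registry, rates, "stillbirth")
        assert series.expected == (135, 90, 115, 105, 97)
        assert series.averted == (0, 13, 19, 22, 30)
        assert series.total_averted == 84

    def test_conservation(self, reference_registry, rates):
        for outcome in ("neonatal", "stillbirth"):
            series = deaths_averted(reference_registry, rates, outcome)
            assert series.total_averted == \
                series.total_expected - series.total_observed

    def test_steady_state_realized_registry_averts_nothing(self):
        registry = [AnnualOutcome(2012 + t, 10000, 310, 120) for t in range(4)]
        rates = baseline_rates_from(registry, 2012)
        series = deaths_averted(registry, rates, "neonatal")
        assert series.total_averted == 0
        assert set(series.averted) == {0}

    def test_negative_averted_propagates(self):
        registry = [
            AnnualOutcome(2012, 10000, 100, 50),
            AnnualOutcome(2013, 10000, 150, 50),
        ]
        rates = baseline_rates_from(registry, 2012)
        series = deaths_averted(registry, rates, "neonatal")
        assert series.averted[-1] == -50
        assert series.total_averted == -50

    def test_missing_baseline_year_is_configuration_error(self):
        registry = [AnnualOutcome(2013, 1000, 10, 5)]
        with pytest.raises(ConfigurationError):
            deaths_averted(registry, BaselineRates(0.03, 0.01, 2012), "neonatal")

    @given(
        base_deaths=st.integers(1, 400),
        deliveries=st.lists(st.integers(100, 20000), min_size=1, max_size=6),
        observed=st.integers(0, 99),
    )
    @settings(max_examples=50, deadline=None)
    def test_averted_monotone_in_baseline_rate(self, base_deaths, deliveries, observed):
        """For fixed observed deaths, a higher baseline rate never
        lowers the averted total."""
        registry = [AnnualOutcome(2012, 10000, base_deaths, 0)] + [
            AnnualOutcome(2013 + i, n, min(observed, n), 0)
            for i, n in enumerate(deliveries)
        ]
        low = baseline_rates_from(registry, 2012)
        high = BaselineRates(min(1.0, low.nmr * 1.5), low.sbr, 2012)
        averted_low = deaths_averted(registry, low, "neonatal").total_averted
        averted_high = deaths_averted(registry, high, "neonatal").total_averted
        assert averted_high >= averted_low


class TestRegistryIO:
    def test_roundtrip(self, reference_registry, tmp_path):
        path = tmp_path / "reg.csv"
        write_registry(reference_registry, path)
        assert read_registry(path) == list(reference_registry)

    def test_frame_columns(self, reference_registry):
        frame = registry_to_frame(reference_registry)
        assert list(frame.columns) == \
            ["year", "deliveries", "neonatal_deaths", "stillbirths"]

    def test_invalid_counts_rejected(self):
        with pytest.raises(DomainError):
            AnnualOutcome(2012, 100, 101, 0)

    def test_validate_flags_duplicates_and_gaps(self):
        rows = [
            AnnualOutcome(2012, 100, 1, 0),
            AnnualOutcome(2012, 100, 1, 0),
            AnnualOutcome(2015, 100, 1, 0),
        ]
        findings = validate_registry(rows)
        severities = {sev for sev, _ in findings}
        assert "error" in severities and "warning" in severities

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"year": [2012]}).to_csv(path, index=False)
        with pytest.raises(ConfigurationError):
            read_registry(path)
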