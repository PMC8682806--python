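"""Exposure-response risk, person-days and uncertainty propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spillsim import health
from spillsim.dispersion import PM25Field
from spillsim.environment import PopulationGrid
from spillsim.grids import GridSpec


def spatial_grid(n=4):
    return GridSpec(lat_min=14.0, lat_max=14.0 + n, lon_min=42.0, lon_max=42.0 + n, cell_size=1.0)


def pm_field(conc, daily=None, rate=0.008, rate_sd=0.002):
    conc = np.asarray(conc, dtype=float)
    g = GridSpec(
        lat_min=14.0, lat_max=14.0 + conc.shape[0],
        lon_min=42.0, lon_max=42.0 + conc.shape[1], cell_size=1.0,
    )
    return PM25Field(
        grid=g, concentration=conc,
        daily=[conc] if daily is None else daily,
        scenario="test", conversion_rate=rate, conversion_rate_sd=rate_sd,
        ensemble_size=1, mass_audit={},
    )


def pop_grid(counts):
    counts = np.asarray(counts)
    g = GridSpec(
        lat_min=14.0, lat_max=14.0 + counts.shape[0],
        lon_min=42.0, lon_max=42.0 + counts.shape[1], cell_size=1.0,
    )
    return PopulationGrid(grid=g, count=counts)


class TestSdFromCi:
    def test_degenerate_ci_gives_zero(self):
        assert health.sd_from_ci(1.1, 1.1) == 0.0

    def test_formula_value(self):
        # ln(1.1/0.9) / (2 x 1.959964), evaluated independently
        expected = np.log(11.0 / 9.0) / (2.0 * 1.959963984540054)
        assert np.isclose(health.sd_from_ci(0.9, 1.1), expected, atol=1e-12)
        assert np.isclose(expected, 0.0511925, atol=1e-6)

    def test_closed_form_inversion(self):
        # upper = lower x e^(2 z) makes sd exactly 1
        upper = float(np.exp(2.0 * 1.959963984540054))
        assert abs(health.sd_from_ci(1.0, upper) - 1.0) < 1e-9

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            health.sd_from_ci(0.0, 1.0)
        with pytest.raises(ValueError):
            health.sd_from_ci(1.2, 1.1)


class TestIrAtConcentration:
    def test_zero_concentration_zero_risk(self):
        for form in ("linear", "log_linear"):
            r = health.RiskFunction(slope=1.0, ci_lower=0.5, ci_upper=1.5, form=form)
            assert health.ir_at_concentration(r, 0.0) == 0.0

    def test_linear_proportionality(self):
        r = health.RiskFunction(slope=1.0, ci_lower=1.0, ci_upper=1.0, form="linear")
        assert np.isclose(health.ir_at_concentration(r, 100.0), 10.0)

    def test_log_linear_compounding(self):
        # two 10 ug/m^3 increments at 1% compound to 2.01%
        r = health.RiskFunction(slope=1.0, ci_lower=1.0, ci_upper=1.0)
        assert np.isclose(health.ir_at_concentration(r, 20.0), 2.01)

    @given(c=st.floats(min_value=0, max_value=2000))
    @settings(deadline=None, max_examples=50)
    def test_nondecreasing_in_concentration(self, c):
        r = health.RiskFunction.burnett_style()
        assert health.ir_at_concentration(r, c + 1.0) >= health.ir_at_concentration(r, c)

    def test_calibration_anchor_530pct_at_1600(self):
        r = health.RiskFunction.burnett_style()
        ir = health.ir_at_concentration(r, 1600.0)
        assert abs(ir - 530.0) / 530.0 < 0.01
        assert np.isclose(r.slope, 1.1567, atol=5e-4)


class TestPopulationWeightedIr:
    RISK = health.RiskFunction.burnett_style()

    def test_uniform_concentration_equals_pointwise(self):
        pm = pm_field(np.full((4, 4), 50.0))
        pop = pop_grid(np.random.default_rng(0).integers(0, 100, (4, 4)))
        expected = health.ir_at_concentration(self.RISK, 50.0)
        assert np.isclose(
            health.population_weighted_ir(pm, pop, self.RISK), expected
        )

    def test_single_populated_cell(self):
        conc = np.zeros((4, 4))
        conc[2, 2] = 80.0
        counts = np.zeros((4, 4), dtype=int)
        counts[2, 2] = 1000
        pm = pm_field(conc)
        ir = health.population_weighted_ir(pm, pop_grid(counts), self.RISK)
        assert np.isclose(ir, health.ir_at_concentration(self.RISK, 80.0))

    def test_no_exposed_population_reports_zero(self):
        pm = pm_field(np.full((4, 4), 1.0))  # everywhere below threshold
        pop = pop_grid(np.full((4, 4), 10))
        assert health.population_weighted_ir(pm, pop, self.RISK) == 0.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            conc = rng.uniform(0, 60, (20, 20))
            counts = rng.integers(0, 1000, (20, 20))
            pm = pm_field(np.zeros((20, 20)))
            pm.concentration = conc
            pm.grid = pop_grid(counts).grid
            num = den = 0.0
            for i in range(20):
                for j in range(20):
                    if conc[i, j] >= 10.0:
                        num += health.ir_at_concentration(self.RISK, conc[i, j]) * counts[i, j]
                        den += counts[i, j]
            expected = num / den if den else 0.0
            got = health.population_weighted_ir(pm, pop_grid(counts), self.RISK)
            assert np.isclose(got, expected)

    def test_weighted_ir_bounded_by_pointwise_extremes(self):
        rng = np.random.default_rng(3)
        conc = rng.uniform(10, 200, (6, 6))
        counts = rng.integers(1, 50, (6, 6))
        pm = pm_field(conc)
        got = health.population_weighted_ir(pm, pop_grid(counts), self.RISK)
        irs = health.ir_at_concentration(self.RISK, conc)
        assert irs.min() - 1e-9 <= got <= irs.max() + 1e-9


class TestPersonDays:
    def test_single_cell_three_days(self):
        counts = np.array([[100]])
        daily = [np.array([[20.0]])] * 3
        assert health.person_days(daily, pop_grid(counts), 10.0) == 300.0

    def test_below_threshold_everywhere(self):
        counts = np.array([[100, 50]])
        daily = [np.array([[5.0, 9.9]])] * 4
        assert health.person_days(daily, pop_grid(counts), 10.0) == 0.0

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            counts = rng.integers(0, 100, (8, 8))
            daily = [rng.uniform(0, 30, (8, 8)) for _ in range(rng.integers(1, 5))]
            expected = sum(
                counts[i, j]
                for d in daily
                for i in range(8)
                for j in range(8)
                if d[i, j] >= 10.0
            )
            assert health.person_days(daily, pop_grid(counts), 10.0) == expected

    def test_monotone_in_duration_and_threshold(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 100, (5, 5))
        daily = [rng.uniform(0, 30, (5, 5)) for _ in range(4)]
        pop = pop_grid(counts)
        pd3 = health.person_days(daily[:3], pop, 10.0)
        pd4 = health.person_days(daily, pop, 10.0)
        assert pd4 >= pd3
        assert health.person_days(daily, pop, 20.0) <= pd4


class TestPropagateUncertainty:
    def test_zero_sds_collapse_ui(self):
        r = health.RiskFunction(slope=1.0, ci_lower=1.0, ci_upper=1.0)
        pm = pm_field(np.full((3, 3), 40.0), rate_sd=0.0)
        pop = pop_grid(np.full((3, 3), 10))
        s = health.propagate_uncertainty(
            pm, pop, r, health.MonteCarloConfig(n_draws=50, seed=0)
        )
        assert np.isclose(s.ir_lo, s.mean_ir) and np.isclose(s.ir_hi, s.mean_ir)

    def test_negative_lower_ui_truncated_to_exact_zero(self):
        # wide slope CI with truncation disabled -> negative 2.5th percentile
        r = health.RiskFunction(slope=0.1, ci_lower=-2.0, ci_upper=2.2)
        pm = pm_field(np.full((3, 3), 40.0), rate_sd=0.0)
        pop = pop_grid(np.full((3, 3), 10))
        s = health.propagate_uncertainty(
            pm, pop, r,
            health.MonteCarloConfig(n_draws=400, seed=1, truncate_draws=False),
        )
        assert s.ir_lo == 0.0
        assert s.possibly_null

    def test_parameter_recovery_with_linear_risk(self):
        # synthetic Normal truth: uniform field, linear form -> IR draw is Normal
        c = 50.0
        slope, lo, hi = 2.0, 1.5, 2.5
        r = health.RiskFunction(slope=slope, ci_lower=lo, ci_upper=hi, form="linear")
        pm = pm_field(np.full((2, 2), c), rate_sd=0.0)
        pop = pop_grid(np.full((2, 2), 10))
        n = 10_000
        s = health.propagate_uncertainty(
            pm, pop, r,
            health.MonteCarloConfig(n_draws=n, seed=2, truncate_draws=False),
        )
        sd_ir = r.slope_sd * 100.0 * c / 10.0  # sd of the IR draws
        mean_ir = slope * c / 10.0
        assert abs(s.mean_ir - mean_ir) < 3 * sd_ir / np.sqrt(n)
        for q, got in ((0.025, s.ir_lo), (0.975, s.ir_hi)):
            z = 1.959963984540054 if q > 0.5 else -1.959963984540054
            expected = mean_ir + z * sd_ir
            se_q = sd_ir * np.sqrt(q * (1 - q) / n) / (
                np.exp(-z**2 / 2) / np.sqrt(2 * np.pi)
            )
            assert abs(got - expected) < 3 * se_q


class TestRiskPresets:
    def test_anchor_consistency_of_ci(self):
        r = health.RiskFunction.burnett_style()
        assert np.isclose(health.ir_at_concentration(r, 1600.0, r.ci_lower), 460.0, rtol=1e-6)
        assert np.isclose(health.ir_at_concentration(r, 1600.0, r.ci_upper), 590.0, rtol=1e-6)

    def test_alternative_presets_well_formed(self):
        for r in (health.RiskFunction.wei_style(), health.RiskFunction.kloog_style()):
            assert r.ci_lower <= r.slope <= r.ci_upper
            assert r.slope_sd > 0
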