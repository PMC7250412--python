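import math

import numpy as np
import pytest

from clotsim.scenarios import (
    ANTI,
    NEUTRAL,
    PRO,
    LysisMetrics,
    Scenario,
    classify_txa_effect,
    compute_lysis_metrics,
    local_sensitivity,
    run_dose_sweep,
    run_knockout_panel,
    run_tpa_upa_balance,
)
from clotsim.simulate import SolverSettings, TimeCourse


def synthetic_tc(times, fibrin, ap=None):
    times = np.asarray(times, dtype=float)
    cols = [np.asarray(fibrin, dtype=float)]
    names = ["fibrin"]
    if ap is not None:
        cols.append(np.asarray(ap, dtype=float))
        names.append("AP")
    return TimeCourse(times, np.column_stack(cols), names)


class TestScenario:
    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            Scenario(txa=-1e-6)

    def test_none_means_packaged_default(self):
        ov = Scenario(tpa=2.5e-9).overrides()
        assert "AP" not in ov and "A2M" not in ov
        assert ov["tPA"] == 2.5e-9

    def test_zero_is_explicit_knockout(self):
        ov = Scenario(a2m=0.0).overrides()
        assert ov["A2M"] == 0.0


class TestComputeLysisMetrics:
    def test_constant_fibrin(self):
        tc = synthetic_tc([0, 100, 200], [1e-6, 1e-6, 1e-6])
        m = compute_lysis_metrics(tc)
        assert m.lysis_time_50 is None
        assert m.percent_fibrin_remaining_at_end == 100.0

    def test_linear_decay_midpoint(self):
        # rise to 1 uM at t=100, linear fall to 0 at t=500 -> LT50 = 300 s
        tc = synthetic_tc([0, 100, 500], [0.0, 1e-6, 0.0])
        m = compute_lysis_metrics(tc)
        assert m.fibrin_peak == pytest.approx(1e-6)
        assert m.t_peak == 100.0
        assert m.lysis_time_50 == pytest.approx(300.0)

    def test_invariant_to_appending_post_lysis_zeros(self):
        tc1 = synthetic_tc([0, 100, 500], [0.0, 1e-6, 0.0])
        tc2 = synthetic_tc([0, 100, 500, 600, 700], [0.0, 1e-6, 0.0, 0.0, 0.0])
        m1, m2 = compute_lysis_metrics(tc1), compute_lysis_metrics(tc2)
        assert m1.lysis_time_50 == m2.lysis_time_50
        assert m1.fibrin_peak == m2.fibrin_peak
        assert m1.t_peak == m2.t_peak

    def test_missing_fibrin_rejected(self):
        tc = TimeCourse(np.array([0.0]), np.array([[1.0]]), ["X"])
        with pytest.raises(ValueError, match="fibrin"):
            compute_lysis_metrics(tc)

    def test_ap_depletion_interpolated(self):
        tc = synthetic_tc([0, 100, 200], [1e-6, 1e-6, 1e-6],
                          ap=[1e-6, 1e-6, 0.0])
        m = compute_lysis_metrics(tc)
        # crosses 1% of initial on the linear fall between 100 and 200 s
        assert m.time_of_ap_depletion == pytest.approx(199.0)

    def test_zero_fibrin_everywhere(self):
        tc = synthetic_tc([0, 100], [0.0, 0.0])
        m = compute_lysis_metrics(tc)
        assert m.lysis_time_50 is None
        assert m.percent_fibrin_remaining_at_end == 100.0

    def test_threshold_configurable(self):
        tc = synthetic_tc([0, 100, 500], [0.0, 1e-6, 0.0])
        m = compute_lysis_metrics(tc, threshold_fraction=0.25)
        assert m.lysis_time_50 == pytest.approx(400.0)


class TestClassification:
    DOSES = [0.0, 1e-6, 1e-5]

    def test_strictly_increasing_is_anti(self):
        assert classify_txa_effect(self.DOSES, [100.0, 150.0, 300.0]) == ANTI

    def test_strictly_decreasing_is_pro(self):
        assert classify_txa_effect(self.DOSES, [300.0, 150.0, 100.0]) == PRO

    def test_flat_within_tolerance_is_neutral(self):
        assert classify_txa_effect(self.DOSES, [100.0, 103.0, 99.0]) == NEUTRAL

    def test_mixed_is_neutral(self):
        assert classify_txa_effect(self.DOSES, [100.0, 300.0, 100.0]) == NEUTRAL

    def test_undefined_counts_as_infinite(self):
        assert classify_txa_effect(self.DOSES, [100.0, 200.0, None]) == ANTI
        assert classify_txa_effect(self.DOSES, [None, 200.0, 100.0]) == PRO

    def test_all_undefined_is_neutral(self):
        assert classify_txa_effect(self.DOSES, [None, None, None]) == NEUTRAL

    def test_dose_order_does_not_matter(self):
        assert classify_txa_effect([1e-5, 0.0, 1e-6], [300.0, 100.0, 150.0]) == ANTI

    def test_tolerance_configurable(self):
        lt = [100.0, 104.0, 108.0]
        assert classify_txa_effect(self.DOSES, lt, rel_tolerance=0.10) == NEUTRAL
        assert classify_txa_effect(self.DOSES, lt, rel_tolerance=0.01) == ANTI


class TestSweepDrivers:
    def test_empty_dose_list(self, full_network):
        result = run_dose_sweep(Scenario(tpa=2.5e-9), [], network=full_network)
        assert result.doses == [] and result.metrics == []
        assert result.to_frame().empty

    def test_negative_dose_rejected(self, full_network):
        with pytest.raises(ValueError):
            run_dose_sweep(Scenario(), [-1e-6], network=full_network)

    def test_doses_deduplicated(self, full_network):
        settings = SolverSettings(t_end=60.0, output_points=5)
        result = run_dose_sweep(Scenario(solver=settings), [0.0, 0.0, 1e-6],
                                network=full_network)
        assert result.doses == [0.0, 1e-6]

    def test_knockout_panel_requires_upa(self, full_network):
        with pytest.raises(ValueError, match="uPA"):
            run_knockout_panel(Scenario(tpa=2.5e-9), network=full_network)

    def test_balance_requires_knockout_regime(self, full_network):
        with pytest.raises(ValueError, match="A2M"):
            run_tpa_upa_balance(Scenario(upa=5e-9), network=full_network)
        with pytest.raises(ValueError, match="uPA"):
            run_tpa_upa_balance(Scenario(a2m=0.0, a1at=0.0), network=full_network)

    def test_sweep_table_columns(self, fig4_sweep):
        frame = fig4_sweep.to_frame()
        assert list(frame["txa_dose_M"]) == fig4_sweep.doses
        assert "lysis_time_50_s" in frame.columns

    def test_provenance_echoed(self, fig5_panels):
        tc = fig5_panels["D"].timecourses[0.0]
        assert tc.scenario_provenance["scenario"]["upa"] == 5e-9


class TestPlasminGenerationParadox:
    def test_more_plasmin_generated_yet_slower_lysis_under_a2m(self, fig5_panels):
        """Cumulative activation rises with TXA while fibrin survives better."""
        panel = fig5_panels["A"]
        tc_lo, tc_hi = panel.timecourses[0.0], panel.timecourses[3470e-6]

        def generated(tc):
            remaining = sum(tc.final(s) for s in ("Pg", "Pgx", "Pgy", "Pgxy"))
            return tc["Pg"][0] - remaining

        assert generated(tc_hi) > generated(tc_lo)
        m_lo = panel.metrics[panel.doses.index(0.0)]
        m_hi = panel.metrics[panel.doses.index(3470e-6)]
        assert m_hi.percent_fibrin_remaining_at_end > m_lo.percent_fibrin_remaining_at_end


class TestLocalSensitivity:
    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            local_sensitivity(Scenario(upa=5e-9), "not_a_parameter")

    def test_kon_y_sensitivity_is_negligible(self):
        """Equilibrium control: rescaling the y-site on-rate (Kd fixed) by
        an order of magnitude leaves the lysis time essentially unchanged."""
        base = Scenario(upa=5e-9, a2m=0.0, a1at=0.0, txa=14e-6)
        result = local_sensitivity(base, "kon_y", delta=9.0)
        spread = abs(result.lysis_time_high - result.lysis_time_low)
        assert spread / result.lysis_time_low < 0.02

    def test_txa_dose_sensitivity_positive_in_anti_regime(self):
        base = Scenario(tpa=2.5e-9, upa=5e-9, a2m=0.0, a1at=0.0, txa=3e-6)
        result = local_sensitivity(base, "TXA", delta=0.5)
        assert result.derivative > 0

    def test_requires_positive_base_dose_for_txa(self):
        with pytest.raises(ValueError):
            local_sensitivity(Scenario(upa=5e-9), "TXA")
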