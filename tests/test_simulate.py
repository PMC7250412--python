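import numpy as np
import pytest

from clotsim.fixtures import FixtureSpec, make_fixture
from clotsim.network import (
    MASS_ACTION_IRREVERSIBLE,
    KineticLaw,
    Reaction,
    ReactionNetwork,
    Species,
)
from clotsim.scenarios import Scenario, compute_lysis_metrics, run_scenario
from clotsim.simulate import (
    SolverFailure,
    SolverSettings,
    TimeCourse,
    build_rhs,
    instantaneous_fluxes,
    simulate,
)


class TestSolverSettings:
    def test_defaults(self):
        s = SolverSettings()
        assert s.rtol == 1e-8 and s.atol == 1e-14 and s.t_end == 7200.0

    @pytest.mark.parametrize("bad", [dict(t_end=0), dict(rtol=0), dict(atol=-1e-9)])
    def test_invalid(self, bad):
        with pytest.raises(ValueError):
            SolverSettings(**bad)

    def test_explicit_grid_must_increase(self):
        with pytest.raises(ValueError):
            SolverSettings(output_times=[0.0, 1.0, 1.0]).grid()


class TestBuildRhs:
    def test_first_order_decay_derivative(self):
        net = ReactionNetwork(
            [Species("A", 1e-6, "uM"), Species("B", 0.0, "uM")],
            [Reaction("r", (("A", 1),), (("B", 1),),
                      KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": 0.1}))],
        )
        rhs = build_rhs(net)
        dy = rhs(0.0, np.array([1e-6, 0.0]))
        assert dy[0] == pytest.approx(-1e-7)
        assert dy[1] == pytest.approx(+1e-7)

    def test_no_reactions_zero_derivative(self):
        net = ReactionNetwork([Species("A", 1e-6, "uM")], [])
        rhs = build_rhs(net)
        assert np.all(rhs(0.0, np.array([1e-6])) == 0.0)

    def test_rhs_is_stoichiometry_times_fluxes(self, packaged_network):
        # oracle composition: dy/dt == N @ instantaneous_fluxes at t=0
        y0 = packaged_network.initial_state({"tPA": 2.5e-9, "TXA": 5e-6})
        rhs = build_rhs(packaged_network)
        N = packaged_network.stoichiometric_matrix().astype(float)
        expected = N @ instantaneous_fluxes(packaged_network, y0)
        np.testing.assert_allclose(rhs(0.0, y0), expected, rtol=1e-12)


class TestInstantaneousFluxes:
    def test_zero_state_zero_fluxes(self, packaged_network):
        flux = instantaneous_fluxes(packaged_network, np.zeros(len(packaged_network.species)))
        assert np.all(flux == 0.0)

    def test_dimension_mismatch(self, packaged_network):
        with pytest.raises(ValueError, match="shape"):
            instantaneous_fluxes(packaged_network, np.zeros(3))

    def test_bimolecular_law_definition(self):
        net = ReactionNetwork(
            [Species(n, 1e-6, "uM") for n in "AB"] + [Species("C", 0.0, "uM")],
            [Reaction("r", (("A", 1), ("B", 1)), (("C", 1),),
                      KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": 2.0}))],
        )
        flux = instantaneous_fluxes(net, [1e-6, 1e-6, 0.0])
        assert flux[0] == pytest.approx(2.0 * 1e-12)

    def test_mm_half_saturation_identity(self):
        Km = 5e-6
        net = ReactionNetwork(
            [Species("E", 1e-9, "nM"), Species("S", Km, "uM"), Species("P", 0.0, "uM")],
            [Reaction("r", (("S", 1),), (("P", 1),),
                      KineticLaw("michaelis_menten", {"kcat": 4.0, "Km": Km}),
                      enzyme="E")],
        )
        flux = instantaneous_fluxes(net, [1e-9, Km, 0.0])
        assert flux[0] == pytest.approx(4.0 * 1e-9 / 2)


class TestSimulate:
    def test_reversible_binding_matches_closed_form(self):
        net, analytic = make_fixture(FixtureSpec(
            "reversible_binding", {"kon": 1e6, "koff": 1.0, "A0": 2e-6, "B0": 2e-6}))
        settings = SolverSettings(t_end=20.0, output_points=80)
        tc = simulate(net, settings=settings)
        exact = analytic(tc.times)
        for name in ("A", "B", "C"):
            np.testing.assert_allclose(tc[name][1:], exact[name][1:],
                                       rtol=1e-6, atol=1e-16)

    def test_empty_reaction_list_constant(self):
        net = ReactionNetwork([Species("A", 3e-6, "uM"), Species("B", 1e-9, "nM")], [])
        tc = simulate(net, settings=SolverSettings(t_end=100.0, output_points=11))
        assert np.all(tc["A"] == 3e-6)
        assert np.all(tc["B"] == 1e-9)

    def test_first_row_is_initial_condition(self, packaged_network):
        tc = simulate(packaged_network, {"TXA": 1e-6},
                      SolverSettings(t_end=10.0, output_points=5))
        np.testing.assert_array_equal(
            tc.concentrations[0], packaged_network.initial_state({"TXA": 1e-6}))

    def test_unknown_override_rejected(self, packaged_network):
        with pytest.raises(KeyError):
            simulate(packaged_network, {"nope": 1e-6})

    def test_no_negatives_or_nan_in_output(self, fig4_sweep):
        for tc in fig4_sweep.timecourses.values():
            assert np.all(np.isfinite(tc.concentrations))
            assert np.all(tc.concentrations >= 0.0)

    def test_deterministic_bit_for_bit(self):
        net, _ = make_fixture(FixtureSpec("full_model_subset", {}))
        s = SolverSettings(t_end=100.0, output_points=20)
        a = simulate(net, settings=s)
        b = simulate(net, settings=s)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)

    def test_solver_failure_carries_last_state(self):
        # a blow-up system: autocatalytic growth exceeding any step control
        net = ReactionNetwork(
            [Species("A", 1e-3, "mM"), Species("B", 1e-3, "mM")],
            [Reaction("r", (("A", 1), ("B", 1)), (("A", 2), ("B", 2)),
                      KineticLaw(MASS_ACTION_IRREVERSIBLE, {"k": 1e9}))],
        )
        with pytest.raises(SolverFailure) as err:
            simulate(net, settings=SolverSettings(t_end=1e6, output_points=10))
        assert err.value.last_state is not None


class TestSolverConvergence:
    def test_tolerance_refinement_changes_metrics_below_0p1_percent(self, full_network):
        base = Scenario(upa=5e-9, a2m=0.0, a1at=0.0, txa=14e-6)
        tc = run_scenario(base, full_network)
        refined = Scenario(upa=5e-9, a2m=0.0, a1at=0.0, txa=14e-6,
                           solver=SolverSettings(rtol=5e-9, atol=5e-15))
        tc2 = run_scenario(refined, full_network)
        m1 = compute_lysis_metrics(tc)
        m2 = compute_lysis_metrics(tc2)
        assert m1.lysis_time_50 == pytest.approx(m2.lysis_time_50, rel=1e-3)
        assert m1.fibrin_peak == pytest.approx(m2.fibrin_peak, rel=1e-3)

    def test_time_grid_invariance(self, full_network):
        coarse = Scenario(upa=5e-9, a2m=0.0, a1at=0.0,
                          solver=SolverSettings(output_points=200))
        fine = Scenario(upa=5e-9, a2m=0.0, a1at=0.0,
                        solver=SolverSettings(output_points=2000))
        m_c = compute_lysis_metrics(run_scenario(coarse, full_network))
        m_f = compute_lysis_metrics(run_scenario(fine, full_network))
        assert m_c.lysis_time_50 == pytest.approx(m_f.lysis_time_50, rel=5e-3)


class TestTimeCourse:
    def test_frame_and_tidy_shapes(self):
        tc = TimeCourse(np.array([0.0, 1.0]), np.array([[1.0, 2.0], [3.0, 4.0]]),
                        ["X", "Y"])
        frame = tc.to_frame()
        assert list(frame.columns) == ["X", "Y"]
        tidy = tc.to_tidy()
        assert set(tidy.columns) == {"time_s", "species", "concentration_M"}
        assert len(tidy) == 4

    def test_csv_roundtrip(self, tmp_path):
        tc = TimeCourse(np.array([0.0, 1.0]), np.array([[1.0, 2.0], [3.0, 4.0]]),
                        ["X", "Y"], {"scenario": {"txa": 0.0}})
        path = tmp_path / "tc.csv"
        tc.write_csv(path)
        import pandas as pd

        frame = pd.read_csv(path)
        assert list(frame.columns) == ["time_s", "X", "Y"]
        assert (tmp_path / "tc.csv.provenance.json").exists()
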