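"""Integration correctness: closed forms, conservation, oracle agreement."""

import dataclasses

import numpy as np
import pytest

import oicsim as oc
from oicsim.engine import (
    DAY_MS, HOUR_MS, SolverOptions, SteadyStateError, Trajectory,
    ac_on_fraction, conservation_drift, default_output_grid, integrate,
    receptor_occupancy, steady_state,
)
from oicsim.network import (
    PulseTrain, RateTable, ReactionDef, ReactionNetwork, SpeciesDef,
    build_network,
)
from conftest import rk4_integrate


def _decay_network(k=0.01):
    """Toy A -> 0 network riding on the kdegrade5HT constant."""
    return ReactionNetwork(
        species=(SpeciesDef("A", 1.0, "shared"),),
        reactions=(ReactionDef("D1", ("A",), (), "mass_action",
                               "kdegrade5HT"),),
        rates=RateTable(kdegrade5HT=k),
    )


class TestIntegrate:
    def test_exponential_decay_closed_form(self):
        net = _decay_network(k=0.01)
        traj = integrate(net, t_end=1000.0)
        expected = np.exp(-0.01 * traj.times)
        assert np.allclose(traj["A"], expected, rtol=1e-6, atol=1e-10)

    def test_output_grid_strictly_increasing_and_spans_horizon(self):
        t = default_output_grid(3 * DAY_MS)
        assert (np.diff(t) > 0).all()
        assert t[0] == 0.0 and t[-1] == 3 * DAY_MS

    def test_clamped_occupancy_reaches_binding_isotherm(self, drugs):
        # [OL] clamped at Kd -> 50%; at 9*Kd -> 90%
        drug = drugs["Morphine"]
        for mult, expect in ((1.0, 50.0), (9.0, 90.0)):
            net = build_network(drug=drug).with_initial(
                OL=mult * drug.kd_uM).with_clamped("OL")
            traj = integrate(net, t_end=6 * HOUR_MS)
            occ = receptor_occupancy(traj, "MOR")
            assert occ[-1] == pytest.approx(expect, rel=1e-3)

    def test_moiety_conservation_over_two_weeks(self, full_network,
                                                morphine_acute):
        traj, _ = morphine_acute
        drift = conservation_drift(full_network, traj)
        assert len(drift) == 7
        assert max(drift.values()) < 1e-6

    def test_concentrations_remain_nonnegative(self, morphine_acute):
        traj, _ = morphine_acute
        assert traj.concentrations.min() >= 0.0

    def test_deterministic_for_fixed_inputs(self):
        net = build_network(pathways=("serotonin",))
        a = integrate(net, t_end=HOUR_MS)
        b = integrate(net, t_end=HOUR_MS)
        assert np.array_equal(a.concentrations, b.concentrations)


class TestObservables:
    def _traj(self, on, free, inhibited):
        names = ("AC", "AC:alphaS_GTP", "AC:alphaI_GTP")
        conc = np.array([[free], [on], [inhibited]], dtype=float)
        return Trajectory(np.array([0.0]), conc, names)

    def test_fully_activated_gives_one(self):
        assert ac_on_fraction(self._traj(2e-3, 0, 0))[0] == 1.0

    def test_all_free_gives_zero(self):
        assert ac_on_fraction(self._traj(0, 2e-3, 0))[0] == 0.0

    def test_equal_thirds_gives_one_third(self):
        assert ac_on_fraction(self._traj(1., 1., 1.))[0] == pytest.approx(1/3)

    def test_zero_total_ac_is_an_error(self):
        with pytest.raises(ValueError):
            ac_on_fraction(self._traj(0, 0, 0))

    def test_no_ligand_means_zero_occupancy(self, full_network):
        traj = integrate(full_network, t_end=HOUR_MS)
        assert receptor_occupancy(traj, "MOR").max() == 0.0


class TestSteadyState:
    def test_serotonin_arm_matches_hand_solved_balance(self):
        net = build_network(pathways=("serotonin",))
        ss = steady_state(net)
        r = net.rates
        # linear S1-S5 subsystem (receptor sink is negligible):
        # 5HT_IN* = ksyn/(krel+kdegIN), 5HT* = krel*5HT_IN*/kdeg5HT
        in_star = r.ksynthesis5HTIN / (r.krelease5HTIN + r.kdegrade5HTIN)
        ht_star = r.krelease5HTIN * in_star / r.kdegrade5HT
        assert ss[net.species_index("5HT_IN")] == pytest.approx(in_star,
                                                                rel=1e-4)
        assert ss[net.species_index("5HT")] == pytest.approx(ht_star,
                                                             rel=1e-3)

    def test_pulsed_network_has_no_fixed_point(self, drugs):
        net = build_network(drug=drugs["Morphine"], pulse=PulseTrain())
        with pytest.raises(SteadyStateError):
            steady_state(net)

    def test_drug_free_baseline_used_as_normalisation(self, baseline_state,
                                                      full_network):
        # the pre-equilibrated state is stationary: an extra day of
        # integration moves no species by more than integration noise
        traj = integrate(full_network, baseline_state, t_end=DAY_MS)
        rel = np.abs(traj.final_state() - baseline_state) / np.maximum(
            baseline_state, 1e-12)
        assert rel.max() < 1e-5


class TestNumericalProperties:
    def test_rk4_oracle_agreement_over_one_hour(self, full_network,
                                                baseline_state):
        x0 = baseline_state.copy()
        x0[full_network.species_index("OL_Blood")] += 4.7
        lsoda = integrate(full_network, x0, t_end=HOUR_MS,
                          t_eval=np.array([0.0, HOUR_MS]))
        oracle = rk4_integrate(full_network, x0, HOUR_MS, dt=100.0)
        got = lsoda.final_state()
        scale = np.maximum(np.abs(oracle), 1e-12)
        assert np.max(np.abs(got - oracle) / scale) < 1e-4

    def test_halving_tolerances_leaves_recovery_stable(self, drugs,
                                                       baseline_state):
        from oicsim.experiments import TreatmentScenario, run_acute_treatment
        scenario = TreatmentScenario(drugs["Fentanyl"])
        times = []
        for opts in (SolverOptions(),
                     SolverOptions(rel_tol=5e-9, abs_tol=5e-15)):
            _, rep = run_acute_treatment(scenario, options=opts,
                                         baseline_state=baseline_state)
            times.append(rep.recovery_time)
        assert abs(times[1] - times[0]) / times[0] < 1e-3

    def test_observables_invariant_under_time_rescaling(self):
        # ms -> s: every rate constant scales by 1000, trajectories
        # coincide at t/1000, and AC_on is unchanged
        net_ms = build_network(pathways=("serotonin",))
        scaled = dataclasses.replace(
            net_ms.rates, **{f: getattr(net_ms.rates, f) * 1e3
                             for f in ("ksynthesis5HTIN", "krelease5HTIN",
                                       "kdegrade5HTIN", "kdegrade5HT",
                                       "kreuptake5HT", "kbind5HT",
                                       "kunbind5HT", "kactivation",
                                       "kassembly", "khydrolization",
                                       "kACassociation_s",
                                       "kACdissociation_s")})
        net_s = build_network(scaled, pathways=("serotonin",))
        t_ms = np.linspace(0, HOUR_MS, 50)
        a = integrate(net_ms, t_end=HOUR_MS, t_eval=t_ms)
        b = integrate(net_s, t_end=HOUR_MS / 1e3, t_eval=t_ms / 1e3)
        assert np.allclose(ac_on_fraction(a), ac_on_fraction(b),
                           rtol=1e-5, atol=1e-8)
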