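"""Acute-treatment readouts, recovery analysis, degradation sweeps."""

import dataclasses
import math

import numpy as np
import pytest

import oicsim as oc
from oicsim.engine import DAY_MS, HOUR_MS, Trajectory, integrate
from oicsim.experiments import (
    TreatmentScenario, compare_paths, degradation_sweep, depletion_time,
    pathway_independence_check, recovery_time, run_acute_treatment,
)
from oicsim.network import DrugSpec, ReactionDef, build_network


def _camp_traj(times_h, values):
    t = np.asarray(times_h, dtype=float) * HOUR_MS
    return Trajectory(t, np.asarray(values, dtype=float)[None, :], ("cAMP",))


class TestRecoveryTime:
    def test_constant_at_maximum_is_already_recovered(self):
        traj = _camp_traj(np.arange(5), np.ones(5))
        assert recovery_time(traj, "camp") == (0.0, False)

    def test_analytic_crossing_of_dip_and_exponential_return(self):
        # y(t) = 1 - 0.6*exp(-t/tau): crosses 0.8 at t = tau*ln(3)
        tau = 10.0  # hours
        t = np.linspace(0, 100, 4001)
        y = 1.0 - 0.6 * np.exp(-t / tau)
        rec, censored = recovery_time(_camp_traj(t, y), "camp",
                                      threshold_fraction=0.8)
        assert not censored
        assert rec == pytest.approx(tau * math.log(3), abs=1 / 60)

    def test_never_crossing_is_censored_not_an_error(self):
        t = np.linspace(0, 10, 50)
        y = np.concatenate([[1.0], np.full(49, 0.1)])
        rec, censored = recovery_time(_camp_traj(t, y), "camp")
        assert censored and rec == pytest.approx(10.0)

    def test_threshold_must_be_a_fraction(self):
        with pytest.raises(ValueError):
            recovery_time(_camp_traj([0, 1], [1, 1]), "camp",
                          threshold_fraction=1.5)


class TestDepletionTime:
    def _ol_traj(self, times_h, values):
        t = np.asarray(times_h, dtype=float) * HOUR_MS
        return Trajectory(t, np.asarray(values, dtype=float)[None, :],
                          ("OL",))

    def test_pure_first_order_decay_matches_closed_form(self, drugs):
        k = 1e-8  # ms^-1
        c0, ic50 = 4.0, 0.01
        t_h = np.linspace(0, 14 * 24, 2000)
        ol = c0 * np.exp(-k * t_h * HOUR_MS)
        got = depletion_time(self._ol_traj(t_h, ol), drugs["Morphine"], ic50)
        expected = math.log(c0 / ic50) / k / HOUR_MS
        assert got == pytest.approx(expected, rel=1e-4)

    def test_dose_below_ic50_depletes_immediately(self, drugs):
        traj = self._ol_traj([0, 1, 2], [1e-4, 5e-5, 1e-5])
        assert depletion_time(traj, drugs["Morphine"], 0.01) == 0.0


class TestAcuteTreatment:
    def test_zero_dose_needs_no_recovery(self, drugs, baseline_state):
        scenario = TreatmentScenario(drugs["Morphine"], dose=0.0,
                                     horizon=DAY_MS)
        _, rep = run_acute_treatment(scenario,
                                     baseline_state=baseline_state)
        assert rep.recovery_time == 0.0
        assert rep.peak_occupancy == 0.0

    def test_morphine_dose_suppresses_then_recovers(self, morphine_acute):
        traj, rep = morphine_acute
        from oicsim.engine import ac_on_fraction
        ac = ac_on_fraction(traj)
        assert ac.min() < 0.5 * ac.max()          # deep suppression
        assert not rep.censored
        assert 3 * 24 < rep.recovery_time < 12 * 24
        assert rep.peak_occupancy > 90.0

    def test_recovery_ordering_across_default_drugs(self, drugs,
                                                    baseline_state):
        """Morphine is the slowest pharmaceutical opioid to recover from,
        and Endomorphin-2 recovers orders of magnitude faster.  (The
        relative order of Methadone and Fentanyl depends on per-drug
        binding kinetics that the shared-koff default cannot resolve.)"""
        rec = {}
        for name in ("Morphine", "Methadone", "Fentanyl", "Endomorphin-2"):
            scenario = TreatmentScenario(drugs[name])
            _, rep = run_acute_treatment(scenario,
                                         baseline_state=baseline_state)
            rec[name] = rep.recovery_time
        assert rec["Morphine"] > rec["Methadone"]
        assert rec["Morphine"] > rec["Fentanyl"]
        assert rec["Endomorphin-2"] < 0.25 * min(rec["Methadone"],
                                                 rec["Fentanyl"])

    def test_late_tissue_depletion_is_first_order(self, morphine_acute,
                                                  drugs):
        # beyond the blood-transfer transient, tissue drug decays at
        # kdegOL: fit the log-slope over days 3..10
        traj, _ = morphine_acute
        ol, t = traj["OL"], traj.times
        sel = (t > 3 * DAY_MS) & (t < 10 * DAY_MS)
        slope = np.polyfit(t[sel], np.log(ol[sel]), 1)[0]
        assert -slope == pytest.approx(drugs["Morphine"].kdegOL, rel=0.02)


class TestPathwayIndependence:
    def test_acute_morphine_leaves_serotonin_untouched(self, drugs):
        scenario = TreatmentScenario(drugs["Morphine"], horizon=2 * DAY_MS)
        out = pathway_independence_check(scenario)
        assert out["passed"]
        assert out["max_relative_difference"] < 1e-6

    def test_detector_flags_an_artificial_cross_reaction(self, drugs,
                                                         baseline_state):
        # add OL + 5HT -> OL (opioid catalyses serotonin loss): the 5HT
        # paths must now diverge between dosed and drug-free runs
        net = build_network(drug=drugs["Morphine"])
        cross = ReactionDef("X1", ("5HT", "OL"), ("OL",), "mass_action",
                            "kbind5HT")
        coupled = dataclasses.replace(net,
                                      reactions=net.reactions + (cross,))
        grid = np.linspace(0, 2 * DAY_MS, 200)
        x_dosed = baseline_state.copy()
        x_dosed[coupled.species_index("OL_Blood")] += 4.7
        dosed = integrate(coupled, x_dosed, 2 * DAY_MS, t_eval=grid)
        free = integrate(coupled, baseline_state, 2 * DAY_MS, t_eval=grid)
        diffs = compare_paths(dosed, free, ("5HT", "5HTR4:5HT"))
        assert max(diffs.values()) > 1e-3


@pytest.fixture(scope="module")
def small_sweep():
    return degradation_sweep(
        kdeg_values=[1e-8, 1e-7, 1e-6],
        kd_grid=[0.57], dose_grid=[0.01, 1.0],
    )


class TestDegradationSweep:

    def test_recovery_monotone_nondecreasing_in_dose(self, small_sweep):
        for res in small_sweep:
            row = res.recovery_matrix[0]
            assert row[1] >= row[0] - 1e-6

    def test_recovery_monotone_nonincreasing_in_kdeg(self, small_sweep):
        at_low_dose = [res.recovery_matrix[0, 0] for res in small_sweep]
        assert at_low_dose == sorted(at_low_dose, reverse=True)

    def test_dose_dependence_flattens_at_fast_degradation(self, small_sweep):
        ranges = [np.ptp(res.recovery_matrix[0]) for res in small_sweep]
        assert ranges == sorted(ranges, reverse=True)

    def test_matrix_shape_and_metadata(self, small_sweep):
        res = small_sweep[0]
        assert res.recovery_matrix.shape == (1, 2)
        assert res.kdeg == 1e-8


class TestK3Sensitivity:
    def test_readouts_respond_monotonically_to_k3(self, drugs,
                                                  baseline_state):
        """The displacement rate k3 has no literature value; this
        documents the sensitivity of the headline readouts to it:
        recovery slows and the inhibition floor deepens as k3 grows."""
        from oicsim.network import RateTable
        recoveries = []
        for k3 in (0.0, 3.5e-3, 7e-3):
            rates = RateTable(k3=k3)
            scenario = TreatmentScenario(drugs["Fentanyl"],
                                         horizon=10 * DAY_MS)
            _, rep = run_acute_treatment(scenario, rates=rates)
            recoveries.append(rep.recovery_time)
        assert all(np.isfinite(recoveries))
        assert recoveries == sorted(recoveries)
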