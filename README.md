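# oicsim

Mass-action ODE model of coupled serotonin and mu-opioid signalling in
the enteric nervous system, built to study opioid-induced constipation
(OIC) in silico: how opioids suppress adenylyl-cyclase (AC) activity and
cAMP while leaving serotonin signalling untouched, and why rapidly
degraded endogenous opioids such as Endomorphin-2 do not constipate the
way pharmaceutical opioids do.

It is aimed at systems-pharmacology and quantitative-biology users who
want a reproducible, scriptable version of this class of GPCR
competition model: a 25-reaction network (serotonergic arm S1–S12,
opioid arm O1–O10, competing cAMP block C1–C3), a stiff-ODE engine,
dose-response fitting, steady-state cAMP calibration, and the acute
opioid-treatment experiments.

## The model in brief

Species concentrations x evolve by the reaction-rate equations

    dx/dt = S · π(x, t)

with stoichiometric matrix S and mass-action propensities π (one
Hill-type production reaction for cAMP).  The serotonin receptor 5HTR4
(Gs-coupled) and the mu-opioid receptor MOR (Gi-coupled) compete for AC
through their G-protein cycles; the activated fraction

    AC_on = [AC:αS-GTP] / ([AC] + [AC:αS-GTP] + [AC:αI-GTP])

drives cAMP production:

    d[cAMP]/dt = −k1·[cAMP] + k2 · (AC_on/EC50)^n / (1 + (AC_on/EC50)^n)

so that the steady state is cAMP* = (k2/k1)·H(AC_on) — the closed form
used to calibrate (k2/k1, EC50, n) from dose-response data.  Dose-
response curves are fitted with a four-parameter logistic in log-dose;
pIC50 = −log10(IC50 in molar).  Opioids are parameterised by affinity
(Kd), a shared unbinding rate (kon = koff/Kd), a tissue degradation rate
kdegOL, and an equianalgesic dose administered into a blood compartment.
See `docs/methods.md` for assumptions, units, and protocol details.

## Worked example

```python
import oicsim as oc
from oicsim.doseresponse import simulate_inhibition_curve, fit_hill, pic50
from oicsim.experiments import TreatmentScenario, run_acute_treatment

drugs = oc.default_drugs()

# potency of Morphine at inhibiting cAMP (forskolin-type assay)
doses, resp = simulate_inhibition_curve(drug=drugs["Morphine"])
fit = fit_hill(doses, resp, "fall")
print(f"Morphine IC50 {fit.ic50:.2e} uM  pIC50 {pic50(fit):.2f}")

# acute 4.7 uM Morphine dose on the full network
traj, rep = run_acute_treatment(TreatmentScenario(drugs["Morphine"]),
                                ic50=fit.ic50)
print(f"recovery {rep.recovery_time/24:.1f} d  "
      f"depletion-to-IC50 {rep.depletion_time_to_ic50/24:.1f} d  "
      f"peak occupancy {rep.peak_occupancy:.1f}%")
```

prints

```
Morphine IC50 5.21e-03 uM  pIC50 8.28
recovery 6.4 d  depletion-to-IC50 7.9 d  peak occupancy 97.9%
```

i.e. Morphine half-inhibits cAMP at ~5 nM (about 15-fold below its Kd —
receptor reserve), and after an acute equianalgesic dose the activated
AC pool needs ~6 days to climb back to 80% of its baseline while nearly
all mu-opioid receptors were occupied at the peak.

The same pipeline is scriptable from the shell:

```bash
oic build-network --out results        # SBML + parameter sheet
oic doseresponse --drug Fentanyl       # inhibition curve + 4PL fit
oic acute --drug Morphine              # recovery/depletion/occupancy
oic sweep --kdeg 1e-8 --kdeg 1e-7      # Kd x dose recovery heatmaps
oic calibrate                          # synthetic cAMP calibration round trip
```

Each subcommand accepts `--config` (YAML overriding any rate constant,
initial concentration or drug definition), `--out` and `--seed`, and
writes the fully-resolved configuration next to its results.

## Layout

```
src/oicsim/
  network.py       species, reactions, rates, drugs, stoichiometry
  engine.py        LSODA integration, observables, steady states
  doseresponse.py  agonist/inhibition assays, 4PL fits, EC50/IC50/pIC50
  calibration.py   steady-state cAMP law, synthetic data, inference
  experiments.py   acute treatments, recovery/depletion, kdeg sweeps
  config.py        YAML configuration, provenance, parameter sheets
  sbml.py          SBML L3 export/import
  cli.py           the `oic` command group
```
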