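# Methods

## The model

`oicsim` simulates how opioids suppress cAMP signalling in enteric
neurons while serotonin signalling keeps running.  Two GPCR arms
converge on one effector, adenylyl cyclase (AC):

* **Serotonergic arm (S1–S12).** Serotonin (5HT) is synthesised inside
  enterochromaffin cells (species `5HT_IN`), released, degraded and
  taken back up; extracellular 5HT binds the Gs-coupled receptor 5HTR4;
  the ligand-bound receptor catalyses nucleotide exchange on the Gs
  heterotrimer; GTP-bound alphaS associates with AC to form the active
  complex `AC:alphaS_GTP`, and GTP hydrolysis plus subunit reassembly
  closes the G-protein cycle.
* **Opioid arm (O1–O10).** An opioid ligand (OL) enters the blood
  compartment, transfers to tissue (first order, ~2 h time constant),
  degrades in tissue at `kdegOL`, binds the Gi-coupled mu-opioid
  receptor (MOR) and drives the analogous Gi cycle; GTP-bound alphaI
  sequesters AC into the inhibited complex `AC:alphaI_GTP`.
* **Competing block (C1–C3).** cAMP is produced through a Hill function
  of the activated AC fraction `AC_on = AC:alphaS_GTP / AC_total` and
  degraded first order; activated alphaI additionally displaces AC out
  of the stimulatory complex (C3).

All propensities are mass action except the Hill production C1.  The
reaction-rate equations dx/dt = S·pi(x) are integrated with LSODA
(the rate constants span seven orders of magnitude, so the system is
stiff).  Concentrations are in uM and time in ms internally; reports
convert to hours and days.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `kbind5HT` / `kunbind5HT` | 4.46e-3 uM^-1 ms^-1 / 5e-8 ms^-1 | 5HT–5HTR4 binding; unbinding is effectively negligible on assay timescales |
| `kactivation` | 0.2 uM^-1 ms^-1 | receptor-catalysed G-protein activation (both arms) |
| `khydrolization` | 6.7e-5 ms^-1 | GTPase clock (~15 s); sets the standing G-alpha-GTP levels |
| `kACassociation`/`kACdissociation` | 3.5e-3 / 3.3e-6 | AC capture and release by G-alpha (~5 min residence) |
| `k3` | 3.5e-3 uM^-1 ms^-1 | alphaI displacement of AC from the active complex; no literature value, defaulted to the AC association rate (same class of molecular event) and exposed in config |
| `koff` (drugs) | 5e-5 ms^-1 | shared unbinding rate; kon = koff/Kd per ligand |
| `kdegOL` | 1e-8 ms^-1 (pharmaceutical), 1.02e-4 (Endomorphin-2) | tissue drug degradation, the key distinction between drug classes |
| `k1`, `k2`, `EC50_hill`, `n_hill` | 6.1e-3, 141.3, 135, 2.44 | cAMP degradation/production Hill law |
| `AC` initial | 2e-3 uM | total AC pool (the source table prints an implausible 2e-34; we use 2e-3, configurable) |

Drug affinities (Kd, nM): Morphine 76.08, Methadone 41.92, Fentanyl
0.57, Endomorphin-2 2.33; equianalgesic acute doses 4.7, 0.2, 0.01 and
1425.51 uM.

### Why koff = 5e-5 ms^-1

Only Kd values are available per drug, so the kon/koff split is a
package choice.  Published MOR agonist association rates sit in the
1e5–1e8 M^-1 s^-1 range; with kon = koff/Kd, koff = 5e-5 ms^-1
(receptor residence ~20 s) puts every ligand inside that range.  The
choice also has to be *kinetically consistent with the assays*: the
forskolin-type inhibition assay reads out 30 minutes after drug
application, and the active AC pool self-relaxes with a ~5-minute time
constant, so receptor binding must equilibrate within seconds-to-
minutes for any dose dependence to be observable at all.  A residence
time of hours would make the potency assay blind and would let the
receptor act as a slow ligand sink.  During the multi-day recovery
experiments occupancy then tracks the tissue concentration
quasi-statically, which is also what makes the depletion readout agree
with the first-order closed form ln(C0/IC50)/kdegOL.

### Ligand bookkeeping on unbinding

Unbinding reactions return the ligand (5HTR4:5HT → 5HTR4 + 5HT,
MOR:OL → MOR + OL).  A variant that destroys the ligand on unbinding is
available (`release_ligand_on_unbind=False`); it is not the default
because receptor-mediated destruction at flux koff·[MOR:OL] would
dominate tissue clearance for low-dose/high-affinity ligands (a
0.01 uM Fentanyl dose would drain through 5e-6 uM of receptors in
hours, contradicting the days-long depletion the degradation rate
implies).

## Assay protocols

**Agonist (5HT → AC activation).** A serotonin bolus is the initial
condition of the serotonergic arm with endogenous synthesis/release
silenced, and the response is the plateau (maximum) AC_on within a 4 h
window.  A clamped-5HT true steady state is not usable here: the
printed binding constants give a receptor-level Kd of ~1e-5 uM, so
steady-state occupancy saturates three decades below the reported EC50;
the transient-exposure protocol (bolus degraded at `kdegrade5HT`,
integrated exposure dose/kdeg) is the reading consistent with the rate
table.  The half-maximal bolus for occupancy alone is
ln2·kdeg/kbind ≈ 1.55 uM, shifted left by downstream receptor reserve.
Because the reserve grows with receptor density, the fitted EC50 falls
from ~1.0 uM at 5e-6 uM receptors to ~0.25 uM at 5e-5 uM — Emax rises
with density as reported for this system, but the EC50
density-*insensitivity* reported alongside it is not reproducible from
the printed rate table (see Limitations).

**Inhibition (forskolin-type).** All AC starts in `AC:alphaS_GTP` (the
G-alphaS it carries comes on top of the resting heterotrimer pool), the
serotonergic drive is off, and the opioid is clamped at a constant bath
concentration, mimicking an in-vitro incubation.  The readout is the
cAMP level after 30 minutes, normalised to the drug-free control.
Clamping matters for two reasons: Endomorphin-2 would otherwise degrade
out of the bath within seconds (tau ~10 s), and nanomolar baths would
deplete by receptor binding.  IC50s come out ~1.2 log units below Kd —
receptor reserve generated by the catalytic Gi cycle plus the C3
displacement reaction — so pIC50 > pKd for every ligand.

**Acute treatment.** The drug-free full network is pre-equilibrated for
24 h (it converges in minutes of simulated time; 24 h is margin), the
dose is added to the blood compartment, and the system is followed for
14 days on a grid that is log-dense over the first hour and hourly
afterwards (interpolation error of recovery times well under one
minute).  Recovery is the first post-nadir return of the observable to
80% of its maximal observed level (the pre-dose plateau is included in
the maximum).  The same 80% rule is applied to the cAMP path in the
degradation sweep; cAMP is a convex monotone transform of AC_on, so its
recovery lags the AC readout slightly.

**Degradation sweep.** Recovery times over a log-spaced (Kd × dose)
grid at fixed koff, kon = koff/Kd per cell, for several `kdegOL`
values; the 2-day iso-contour is interpolated per Kd row in log dose.
The drug-free equilibrium is computed once and shared by all cells.

## cAMP calibration and the synthetic data generator

The cAMP balance has the closed-form steady state
cAMP* = (k2/k1)·H(AC_on).  Steady-state data constrain only k2/k1
together with (EC50, n) — scaling k1 and k2 jointly changes nothing —
so the inference fixes k1 and fits k2, EC50 and n (bounded least
squares in log space, five multi-starts, seeded).  The calibration
layer feeds the Hill law activation readouts in *percent* of the AC
pool: with a midpoint of 135, fraction-scale inputs (≤1) would sit so
deep in the power-law regime that EC50 and k2 would be exactly
degenerate, while percent-scale readouts approach the midpoint and
constrain it.

The synthetic generator emulates a cAMP-accumulation dose-response
experiment at several receptor densities: activation from the simulated
serotonin arm (or any supplied activation model), the steady-state
law, and multiplicative lognormal noise with a prescribed CV
(cAMP assays are positive-valued with roughly constant CV; no noise
model is stated for the reference data).  What the round trip does
show: the inference is unbiased at 5% noise (Monte-Carlo over 100
seeds) with per-seed midpoint errors within a factor ~1.2.  What it
does not show: anything about the real reference measurements —
plate-to-plate variance structure, saturation artefacts and receptor
expression uncertainty are not emulated.

## Numerical choices

* LSODA, rtol 1e-8, atol 1e-14; halving tolerances moves recovery
  times by <0.1%.
* Negative excursions beyond −1e-12 uM abort the run; smaller ones are
  clipped to zero.
* Steady-state detection: relative change of every species below 1e-9
  per simulated hour; non-convergence names the slowest species.
* An independent fixed-step RK4 integrator (tests) agrees with LSODA to
  <1e-4 relative over an hour of the full stiff system.
* The seven moiety totals (receptors, G-protein subunits, AC) drift by
  <1e-6 relative over 14 simulated days (observed ~1e-15..1e-14).
* Recovery/depletion crossings are linearly interpolated between grid
  points; ties resolve to the first crossing after the global nadir.
* Problem sizes: dose-response curves use 24 log-spaced doses over 6
  decades centred on the drug's Kd; the density sweep uses 5 densities
  in [5e-6, 5e-5] uM; sweep grids default to 12×12 per kdeg.

## Known limitations

* **Serotonin EC50 scale.** Under the bolus protocol the fitted EC50
  averages ~0.6 uM over the sampled densities (reported: 0.33 uM) and
  varies ~4x across the density decade (reported: insensitive).  Both
  discrepancies trace to the printed rate table — occupancy saturation
  at clamped 5HT rules out a steady-state protocol, and the
  receptor-reserve gain is necessarily density-dependent.  Matching
  both reported numbers simultaneously would require receptor-level
  binding constants (or a release calibration) that are not printed.
* **Per-drug binding kinetics.** With a shared koff, recovery ordering
  follows ln(dose/Kd): Morphine slowest, Endomorphin-2 orders of
  magnitude fastest, but Fentanyl comes out slower than Methadone
  (the reported inversion needs per-drug kinetics that are not
  printed).  Equally, the reported 3-day recovery of the
  kdegOL = 1e-7 ms^-1 sweep cell is not reachable: at that degradation
  rate the tissue drug is gone within a day, and only a ~days receptor
  residence could stretch recovery to 3 days — which would contradict
  the inhibition assay entirely.  The package reports the model's own
  value (~0.7 d) rather than tuning for the printed one.
* **k3 sensitivity.** The displacement rate k3 moves both potency and
  recovery readouts (IC50 ~8x, recovery ~1.6x over k3 in [0, 2x
  default]); the default keeps it tied to the AC association rate, and
  the sensitivity is exercised in the test suite.
* No receptor internalisation, no repeated dosing, no spatial
  structure beyond the blood/tissue transfer, no stochastic (SSA)
  simulation, and no mapping from cAMP to defecation frequency.
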