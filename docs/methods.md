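# Methods

## Model structure

The package integrates a 12-dimensional stiff ODE system describing one
representative red blood cell and a finite extracellular compartment:
cell contents Q_Na, Q_K, Q_A, Q_Ca (mmol per liter of original cells,
"Loc"), cell pH, cell water V_w, and the medium tracked as solute
*amounts* plus medium water and pH.  Tracking medium amounts (rather than
concentrations) makes cell+medium conservation of every species and of
water exact by construction at any cell volume fraction (CVF).  Switching
CVF re-sizes the medium compartment at fixed concentrations — the physical
picture of the cell entering a capillary (CVF 0.9) or returning to the
effectively infinite systemic circulation (CVF 10⁻⁵, where a "restore
medium" event also resets the composition to its baseline snapshot).

### Pathways and closures

* **Electrodiffusion.**  All conductive fluxes (ground Na⁺/K⁺/Ca²⁺/anion
  leaks, the four PIEZO1 open-state permeabilities, the Gardos channel)
  use the Goldman constant-field equation, evaluated through `expm1` with
  a series branch below |u| < 10⁻¹⁰ so the Em → 0 limit is exact.
* **Membrane potential.**  Em is not a differential state.  At every
  right-hand-side evaluation it is solved from zero net membrane current
  (including the 3:2 electrogenic pump current) by bracketed Brent
  iteration to machine precision, warm-started from the previous solution.
  This quasi-stationary closure is standard for red-cell models: membrane
  charging (~ms) is orders of magnitude faster than ion shifts, which is
  also why the potential jumps discontinuously at PIEZO1 gating events.
* **Anion and proton chemistry.**  The diffusible anion A⁻ lumps Cl⁻ and
  HCO₃⁻.  The Jacobs–Stewart (JS) cycle is condensed into an electroneutral
  Cl⁻:H⁺ cotransport, first order in the relative displacement of
  [Cl]·[H] from Donnan equilibrium with rate coefficient kJS.  Proton
  loads are buffered linearly (haemoglobin slope β·Hb ≈ 52 mmol/Loc per pH
  unit in the cell; 25 mmol/L per pH unit in the medium); free protons are
  ~10⁻⁵ mmol/L and osmotically negligible.
* **Calcium.**  Free [Ca²⁺]_i is a constant fraction α of the total
  concentration (rapid-buffer closure).  The PMCA is a Michaelis-type,
  electroneutral Ca²⁺:2H⁺ exchanger; the Gardos channel's effective K⁺
  permeability is FKmax scaled by a Hill function (n = 2) of free Ca²⁺.
* **Water.**  Kinetic, Fw = L_p(C_Os − M_Os).  Cell osmolarity counts the
  small ions and impermeant pool ideally, haemoglobin through the virial
  coefficient 1 + 0.0645·c_Hb + 0.0258·c_Hb² (c_Hb in mmol/L water), and
  only the free fraction of calcium.

### Reference state construction

The baseline is built, not assumed.  Given target compositions (cell Na 10,
K 140 mmol/L water; medium Na 140, K 5, A 127, Ca 1.0 mmol/L; pH_o 7.4;
290 mOsm; Em −9 mV; V_w 0.7 L/Loc; Hb 5.25 mmol/Loc ≈ 34 g/dL) the builder
back-computes: the pump rate from its saturation kinetics; ground P_Na and
P_Ca to balance pump extrusion; the cell anion level so the conductive
anion influx replaces the chloride the JS cycle exports while clearing the
pump's proton influx (which also fixes pH_i ≈ 7.25, just off Donnan
equilibrium); ground P_K net of the resting Gardos conductance; and the
impermeant osmolyte pools on both sides from isotonicity.  Because the
species balances close the charge balance identically, the zero-current
solver reproduces the target Em without further adjustment, and every
derivative vanishes to ~10⁻¹³ — the built state is an exact fixed point,
and rebuilding from a built state is idempotent to machine precision.
Infeasible targets (e.g. a resting Gardos conductance exceeding the K⁺
leak budget) raise an error naming the violated species.

### Integration and protocols

Stages are integrated with LSODA at rtol 10⁻⁹ and per-state absolute
tolerances scaled to each variable's magnitude — necessary because the
physiological signals are ~10⁻⁵ relative.  Stage boundaries and the PIEZO1
closure at t_open + OS are segment endpoints, never stepped across.
Output sampling follows the original simulator's controls: "accuracy"
(printed decimals), "epochs" (rows per stage) and "frequency factor" (a
geometric densification of samples toward the stage start, where the
events are).  Runs are deterministic and byte-reproducible.

## Parameters

Fixed by the experimental record and held at those values: PzCa = 70 h⁻¹,
PzA = 50 h⁻¹, PzNa = PzK = 0, OS = 0.4 s, ground anion permeability
PA = 1.2 h⁻¹, PMCA FCamax spanning 4–24 (default 12) mmol/Loc·h.

Calibrated once, at design time, against the behaviours the model family
is required to reproduce (the ~2 mV membrane-potential excursion with
depolarization confined to the open state; Gardos/PMCA fluxes back within
1% of baseline in < 20 s after closure even for the weakest pump; a
swelling peak < 6×10⁻⁵ with residual water influx persisting a few seconds
after egress; a final below-baseline displacement on the 10⁻⁵ scale; and
the weak-pump-lowest-peak ordering across PMCA strengths):

| parameter | default | role |
|---|---|---|
| KmCa | 0.3 µM | PMCA half-saturation; with baseline free Ca 30 nM keeps resting pump turnover low (~1 mmol/Loc·h) so the open-state Ca²⁺ current, not the resting anion displacement, sets the sign of the Em deflection |
| α (free Ca fraction) | 0.3 | effective rapid-buffer ratio; sets the free-Ca relaxation rate and hence the < 20 s clearance at FCamax = 4 |
| FKmax | 0.2 h⁻¹ | maximal Gardos permeability; sets hyperpolarization depth and undershoot scale |
| KCaGardos | 5 µM | places the transit peak free Ca (~4 µM) on the steep part of the Hill curve, so pump strength modulates Gardos activity (peak ordering) while resting activation stays negligible |
| kJS | 1000 mmol/Loc·h | JS turnover per unit relative displacement; sets the minutes-scale exposure of the Gardos dehydration (baseline crossing ~1 min, scaling inversely with kJS) |
| L_p | 4.0 L/(Loc·mOsm·h) | osmotic water conductance; swelling peak at ~1.8 s, residual influx complete within ~5 s |
| FNaKmax, Km(Na), Km(K) | 7.8, 3.3, 0.65 | pump kinetics reproducing ~2.6 mmol/Loc·h resting Na turnover |

These are package defaults, all overridable through `TransportParams` /
`ReferenceTargets`; the back-computed ground permeabilities land at
physiological values (P_Na ≈ 0.017, P_K ≈ 0.015 h⁻¹).

Two structural consequences are worth recording.  First, the open-state
depolarization and the fast weak-pump Ca clearance pull the PMCA operating
point in opposite directions (low resting turnover vs steep response
around baseline); the KmCa/α corner above satisfies both.  Second, the
swelling peak must form *after* the pump strengths have begun to
differentiate the Ca²⁺ trajectories (≳1.5 s) for weak pumps to show the
lowest peaks; with a faster L_p the peak forms at ~1 s and the ordering
degenerates to < 0.3% differences of either sign.  α = 0.3 is an effective
dynamic ratio for the transit-relevant rapidly exchanging pool, larger
than equilibrium free/total Ca ratios measured on longer timescales.

## What the simulations do and do not show

All experiments are self-contained simulations from the built reference
state; there is no external data.  The "synthetic data" of this package
are protocol files and model outputs: they emulate the event structure of
a capillary passage (deformation-gated permeabilities, cell-medium
proportions, reservoir restoration) but idealize PIEZO1 gating as a square
pulse, lump all anion conductances into PzA/PA, omit Mg²⁺, metabolism
(ATP, 2,3-DPG), membrane mechanics and cell-to-cell variability.  Passing
tests therefore certify the homeostatic logic and its parameter
dependences, not channel-level gating kinetics; quantities tied to the
open-state charge flow (peak height, Em excursion) inherit the uncertainty
of the OS×Pz product, which the model shows is the invariant that matters
(halving OS while doubling PzCa changes the Ca load by < 3%).

## Numerical choices and degenerate inputs

Brent brackets for Em are ±150 mV (an error is raised if no zero-current
solution exists there); |Em| > 400 mV anywhere is treated as integrator
blow-up.  Gardos activation at zero Ca, PMCA at zero Ca, the pump at zero
Na and the JS flux at zero reference product all return exactly zero.
Normalized Ca-transient traces with no meaningful signal (rise below 5% of
baseline free Ca, e.g. PzCa = 0) are reported as flat zeros rather than
normalizing noise.  The W1–W4 fluid decomposition defines W2–W4 as
isotonic equivalents of the Gardos/PMCA/JS solute fluxes in excess of the
resting pump-leak recirculation, and W1 by closure, so
Fw = W1 − (W2+W3+W4) holds identically; during the open state W1 is the
PIEZO1-led gain, outside it W1 absorbs the osmotic-lag residual.  The
fixed-step Euler oracle used to certify the production integrator is
first-order: its step must shrink to ~2×10⁻⁷ h inside the CVF-0.9 open
state (fast medium-depletion and water modes), while 10⁻⁵ h suffices on
quiet windows; a Richardson halving check guards every oracle run.

## Known limitations

Single representative cell (no population heterogeneity, though the JS
rate is documented to vary ~13–15% between donors); no senescence or
lifespan accumulation (out of scope here); pH_o dynamics use a fixed
linear plasma buffer; the anion attribution of the open-state conductance
(PzA) is phenomenological and carries no claim that PIEZO1 itself conducts
anions.  Long-horizon runs (the ~10-day recovery of the post-transit
volume displacement at 5% tolerance of the undershoot) assume constant
transport parameters throughout.
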