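# Methods

`afvtrial` is an in-silico drug-trial engine for atrial fibrillation (AF).
It couples a human atrial myocyte model to a 2D monodomain sheet built
from synthetic "electroanatomical" substrates, applies genotype- and
drug-dependent ion-channel scaling, and measures the electrophysiological
and wave-dynamics quantities that clinical modeling studies report:
APD90, conduction velocity (CV), restitution slope (Smax), AF cycle
length (AFCL), dominant frequency (DF), phase singularities (PS), and AF
termination.  This note records the model, the measurement conventions,
the numerical choices, and what the desk-scale defaults do and do not
show.

## Cell model

The ionic model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
myocyte: 21 states — membrane potential V, 15 Hodgkin–Huxley gates (fast
Na m/h/j, transient-outward oa/oi, ultrarapid ua/ui, rapid/slow delayed
rectifier xr/xs, L-type Ca d/f/fCa, SR-release u/v/w) and 5
concentrations (Na_i, K_i, Ca_i, SR uptake and release Ca).  All maximal
conductances and pump/exchanger rates are multiplied by a 13-slot scale
vector (gNa, gK1, gto, gKr, gCaL, gKur, gKs, INaCa_max, INaK_max,
Iup_max, Krel, Caup_max, ACh); the identity vector reproduces the
published model (resting potential ≈ −81 mV, APD90 ≈ 284 ms at a 600-ms
cycle length).  The acetylcholine-activated K⁺ current is carried as a
scale slot with zero baseline conductance, because the condition tables
hold it at 100% everywhere; setting a nonzero conductance activates it.

Genotype and rhythm-state parameterizations are stored verbatim as
percent-of-baseline columns (wild-type/PITX2-deficient × sinus-rhythm/AF).
The AF remodeling of the deficient genotype is documented as applying the
same per-channel percent change as wild-type SR→AF; we keep the stored
column as data and expose the proportionality rule as a *validation*
(`conditions.consistency_report`), because the stored deficient-AF gK1
(1.58) differs from exact derivation (0.71·2.10/0.95 ≈ 1.5695) by a
rounding step.

Drug effects are multiplicative block factors on fixed per-drug channel
subsets (amiodarone, sotalol, dronedarone = class III; flecainide,
propafenone = class IC), two labeled doses each.  The original numeric
percent blocks live in an unavailable supplement; the shipped factors are
**editable defaults** assembled from the patch-clamp literature behind
each drug's channel list, rounded to 0.05 and dose-monotone by
construction.  Every resolved scale vector is recorded per case, so
substituting a different block table is a config change, not a code
change.

## Single-cell protocols

* **Stimulus**: rectangular, 2 ms, twice the diastolic threshold; the
  threshold is found once per parameterization by bisection (capture =
  V crossing 0 mV within 50 ms).
* **APD90**: activation at maximum dV/dt; resting reference is the
  pre-upstroke minimum of the same beat; threshold V_rest + 0.1(V_peak −
  V_rest), crossed with linear interpolation.  Paced APD90 is measured on
  the last of 10 beats at cycle length 600 ms.
* **Restitution**: a decremental ramp, cycle length 600→200 ms in 25-ms
  stages, 8 beats per stage, sampling the last beat of each stage;
  DI = CL − preceding APD90; stages without capture are dropped.  The
  curve APD(DI) = y0 + A1(1 − e^(−DI/τ1)) is fitted by bounded
  least-squares (A1 ≥ 0), and Smax = (A1/τ1)·e^(−DI_min/τ1), the fitted
  slope at the smallest observed DI — the maximum over the observed
  domain for a saturating fit.  If the optimizer fails, the steepest
  finite-difference slope is reported instead and flagged.

## Substrate synthesis

The generator emulates what a clinical mapping study supplies, as a pure
function of (parameters, seed):

* **Geometry**: a monolayer lattice sheet, default 50 × 50 mm at 0.5-mm
  spacing (the study this emulates modeled the left atrium as a
  monolayer; the sheet is its desk-scale stand-in).
* **Bipolar voltage**: a Gaussian random field (correlation length 8 mm)
  mapped through a lognormal quantile transform (σ_ln = 1.2) whose median
  is set so the fraction of nodes below the 0.5-mV low-voltage cutoff
  equals the requested value.  The generator's default is 0.3 (a
  moderately fibrotic AF atrium); the *trial* profile uses 0.2, because
  with fully non-conducting fibrosis a desk-scale sheet percolation-blocks
  somewhere above ~15% fibrotic nodes and no protocol can cross it —
  heavier loads need either the reduced-coupling fibrosis mode or
  full-size geometry.  A ≥500-point subsample emulates catheter mapping
  density, and
  the node-level map is rebuilt from those points by inverse-distance
  weighting (power a = 2, radius 10 mm) — the same interpolation rule the
  clinical pipeline uses, exercised end-to-end.
* **Fibrosis**: per-node Bernoulli draws with a monotone non-increasing
  logistic probability in bipolar voltage (midpoint 0.4 mV, steepness
  10 /mV, ceiling 0.9).  The sharp midpoint concentrates fibrosis in
  low-voltage patches; shallower curves scatter blockers through healthy
  tissue and stop all propagation.  Fibrotic nodes are non-conducting
  (zero-flux holes); a reduced-coupling mode is intentionally not the
  default.
* **Fibers**: rule-based.  `uniform`, `swirl` (tangential field), or
  `random-smooth` (default): a Gaussian-smoothed scalar field scaled to
  ±π/4 around the base angle, smooth by construction (no director
  singularities).
* **Landmarks**: the pacing site and distal ROI sit in viable tissue of
  the largest conducting cluster, near opposite corners — as a catheter
  would be positioned — with a 1.5-mm conducting disc guaranteed around
  the pacing site.  Blindly using corner nodes occasionally lands inside
  scar and silently kills every protocol.
* **Diffusion calibration**: log-space bisection of the longitudinal
  diffusion coefficient D_L until the plane-wave CV on a uniform strand
  matches a target, at the production spacing and dt.  The desk-scale
  default target is 0.25–0.35 m/s: an AF wavelength (CV × APD ≈ 30–45 mm)
  must fit inside a 50-mm sheet for reentry to be possible at all.
  Full-size atria support the clinically reported ≈0.7 m/s; a small sheet
  at that speed can never fibrillate, so desk-scale CVs are a deliberate
  scale compromise, recorded in every manifest.
* **Anisotropy**: D_L/D_T = 2 by default.  At 0.5-mm spacing a 4:1 ratio
  pushes the transverse coupling below the discrete-lattice propagation
  limit of the remodeled cells and waves die; 2:1 stays safely above it
  while preserving directional conduction.

## Tissue solver

Monodomain reaction–diffusion with operator splitting per step: explicit
diffusion on V (finite-volume 5-point axis fluxes with arithmetic-mean
edge diffusivity, plus a centered cross-derivative term away from
boundaries and holes), then the cell-model reaction step on every
conducting node.  No-flux outer boundaries and fibrotic holes are
enforced by zeroed edge weights, so a uniform field diffuses to exactly
zero and total charge is conserved by the axis terms.  Gates advance by
Rush–Larsen exponential updates; V and concentrations by forward Euler.

Step sizes: 0.01 ms for single-cell work (halving dt moves APD90 by
<1 ms), 0.05 ms for tissue.  The tissue kernel uses tabulated
voltage-dependent kinetics (steady states, Rush–Larsen factors,
rectification/pump/exchanger voltage factors on a 0.05-mV grid with
linear interpolation; Ca- and Fn-driven gates stay analytic), which
agrees with the exact path to within a few ms of APD90 and runs ~6×
faster.  Plane-wave CV on the production 0.5-mm grid is below its
continuum value (explicit FD under-resolves the upstroke; convergence to
<5% per spacing halving is reached near 0.1-mm spacing) — the CV
*calibration* is therefore always performed at the production spacing, so
absolute tissue CVs are controlled even where the grid is coarse.
Integration aborts with diagnostics if |V| exceeds 200 mV.

**AF induction.**  Burst pacing (20 stimuli, CL ramped 200→120 ms) is
implemented and available, but on desk-scale sheets it never produced
sustained reentry in a systematic sweep of CV targets, fibrosis loads and
anisotropy — the last burst wave washes out within ~0.5 s.  The default
induction is therefore S1–S2 cross-field: an S1 plane wave from the left
edge, then a perpendicular half-plane S2 (bottom half of the sheet; a
single-quadrant variant is available) delivered shortly after the sheet
center repolarizes behind S1.  The timing is measured from a probe pass
per case, so the S2 lands inside the vulnerable window regardless of how
the condition's drug/genotype changes APD and CV; the half-plane shape
breaks along the whole repolarization tail and seeds a counter-rotating
rotor pair.  This is the standard rotor-initiation protocol for sheet
studies and is fully deterministic.

**Termination** is the earliest post-induction time at which every node
stays below −40 mV for a 500-ms quiescence window; cases active to the
end of the trace are non-terminated.  The desk-scale observation window
is 8 s by default (configurable to the full study's 32 s); shortened
windows are flagged `scaled_down` in the outputs.

## Wave-dynamics measurements

* **LAT**: per-node time of maximal dV/dt within a beat window; nodes
  that never cross −40 mV are missing.
* **CV (reported)**: sheet distance from the pacing site to the distal
  ROI divided by their LAT difference (m/s).
* **AFCL**: per-node mean interval between successive upward −40-mV
  crossings, averaged over nodes with ≥2 activations — computed from
  activation times, *not* as 1/DF, since the two are reported separately.
* **DF**: per-node dominant frequency of mean-subtracted, Hann-tapered V
  in a 3–15 Hz band on ≥2-s windows (≤0.5-Hz resolution); peak DF = max
  over nodes, mean DF = mean, so peak ≥ mean by construction.  Flat nodes
  are excluded.
* **Phase and PS**: instantaneous phase by the analytic signal (Hilbert
  transform) of mean-subtracted V; one AP cycle traverses 2π.  A phase
  singularity is a plaquette whose wrapped phase differences wind to ±2π
  (topological charge ±1).  Tracking is greedy nearest-neighbor across
  frames, charge-respecting, with a 5-mm jump limit.  **PS number is the
  cumulative count of per-frame detections over the analysis window** —
  the only convention consistent with published per-case magnitudes of
  10⁴–10⁵ over 32 s; concurrent counts are ~10⁰–10¹.  PS life span is the
  mean lifetime over tracks (undefined with no tracks).
* **Smax maps**: per-node (DI, APD90) samples from ramp runs are fitted
  node-wise with the single-cell restitution fit; the case value is the
  mean over valid nodes and the argmax node is reported.  In the trial
  pipeline the per-case mean Smax uses the AF-parameterized single-cell
  ramp (the tissue-map variant is available but costs a full 2D ramp run).

## Trial pipeline and statistics

A trial enumerates substrate replicates × genotypes × (baseline + 5 drugs
× 2 doses) — 550 cases at the full-study scale of 25 replicates,
mirroring the 25-baseline + 250-drug case structure per genotype.  Per
case: APD90 (SR scales, CL 600), CV (SR scales, plane-wave at the
substrate's D), Smax (AF scales, restitution ramp), and the 2D AF run
(AF scales, induction + analysis window) for AFCL/DF/PS/termination.
Cases are deterministic given the master seed; per-case seeds expand by a
counter scheme recorded in the manifest, rows are checkpointed as JSON,
and report regeneration from the archive is bit-identical.

Not every desk-scale substrate sustains reentry, just as not every atrium
is clinically inducible; a single 50-mm sheet holds at most one or two
rotors, so baseline AF survives the analysis window on only a
seed-dependent fraction of replicates.
`trial.screen_inducible_substrates` makes the study's inclusion rule
explicit: candidate substrates are screened by their drug-free AF runs,
and wave-dynamic comparisons are restricted to substrates whose baseline
AF outlasts the analysis window in both genotypes (the screening runs are
reused, never repeated).  Termination-rate tables still count every case.

Statistics follow the conventions of the emulated study: equal-variance
Student's t for two-sample contrasts, paired t for dose effects within a
model, Cohen's d (pooled n−1 SD) for effect sizes, and no
multiple-testing correction (noted in the report footer).  For
termination rates the pipeline adds Fisher's exact test on the 2×2
counts; published summary percentages are reproduced by plain count
arithmetic (`termination_rates_from_counts`), separate from the per-case
tables.  Cases that terminate before the analysis window keep NaN
wave-dynamic fields: they are excluded from wave-dynamic summaries but
always counted in termination tables.

## Desk scale: what the defaults show

The emulated study ran 25 patient-specific 3D atria for 32 s each.  The
desk-scale defaults (50-mm sheet, 0.5-mm spacing, 8-s windows, ~10
replicates; the bundled acceptance checks use 2 replicates × 3.5-s
windows to stay inside a CI budget) reproduce *mechanisms and
directions* — genotype ordering of APD90 and Smax, drug-induced AFCL
lengthening and DF/PS reduction, dose monotonicity — not the absolute
tissue means of a patient cohort.  Specifically:

* Absolute APD90 of the wild-type SR parameterization is the canonical
  CRN value (≈286 ms at CL 600), ~17% above the cohort tissue mean
  (243.7 ± 33.8 ms); the deficient-SR value (≈227 ms) sits ~23% above its
  cohort mean (184.4 ± 15.5 ms).  The genotype ordering and the AF-state
  shortening are robustly reproduced.  Cohort means fold in
  patient-specific tissue heterogeneity and the original group's own
  model variant, neither of which a clean single cell can supply.
* PS numbers scale with sheet area and window length and are orders of
  magnitude below full-atria counts; only signs and orderings of
  contrasts are meaningful at desk scale.
* Sheet CV targets (0.25–0.35 m/s) are below the cohort's 0.78 ± 0.32 m/s
  so that reentry fits the sheet (see above).
* Two tissue-level contrasts invert or vanish at desk scale, and the
  bundled checks report them as measured rather than forcing the
  full-size direction.  The genotype ordering of baseline AFCL inverts:
  on a one-rotor sheet the cycle length tracks the cell APD, and the
  wild-type AF cell's APD (≈138 ms) exceeds the deficient cell's
  (≈129 ms), whereas the cohort's longer deficient-model AFCL emerges
  from the organization of multi-wavelet AF on full-size atria.  The
  drug-induced PS-number reduction becomes a null on equal-length
  windows: a sheet carries one rotor pair, so the cumulative PS count is
  set by the window, and the drug effect expresses itself as termination
  instead.  Drug-induced AFCL lengthening (and the corresponding DF
  slowing) does reproduce.

The synthetic substrate also omits, by design: real atrial geometry and
curvature, wall thickness and endo/epicardial bilayers, atlas-derived
fiber maps, pulmonary-vein/appendage anatomy, and multisite induction.
Passing tests therefore demonstrate correct mechanisms under controlled
desk-scale conditions, not patient-level prediction.

## Known limitations

* Drug action is pure conductance scaling — no state-dependent (Markov)
  binding, no pharmacokinetics, no Hill dose–response; dose enters only
  as the two labeled levels.
* The drug block factors are literature-informed defaults, not the
  original study's exact supplement values.
* Fibrosis is binary non-conducting; paracrine/partial-coupling effects
  are not modeled.
* Explicit FD at 0.5-mm spacing under-resolves CV (handled by calibrating
  at production resolution, but absolute CVs at other spacings shift).
* No SR calcium-leak or triggered-activity analysis.
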