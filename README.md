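# afvtrial

Virtual antiarrhythmic-drug (V-AAD) trials on genotype-parameterized
atrial fibrillation models.

`afvtrial` is for computational electrophysiologists and quantitative
cardiology researchers who want a tested, reproducible desk-scale engine
for in-silico AF drug screening: a human atrial myocyte model
(Courtemanche–Ramirez–Nattel) whose channel conductances encode genotype
(wild-type vs heterozygous *PITX2* deficiency), rhythm state (sinus
rhythm vs AF remodeling) and drug block (five drugs, two doses each); a
2D monodomain solver over synthetic fibrotic substrates built the way
clinical electroanatomical maps are built (point-sampled bipolar voltage,
inverse-distance-weighted interpolation, voltage-dependent fibrosis); and
the wave-dynamics measurements such studies report.

## The model in brief

Cell dynamics follow the CRN human atrial action potential model,
dX/dt = f(X) with 21 states, where every maximal conductance g and pump
rate is replaced by s·g with s from a 13-component scale vector.  A
condition (genotype × rhythm × drug × dose) resolves to one scale vector;
e.g. wild-type AF remodeling is gCaL×0.30, gK1×2.10, gto×0.30, …, and a
drug multiplies block factors into its channel subset only.

Tissue propagation is monodomain, ∂V/∂t = ∇·(D∇V) − I_ion/C_m, with an
anisotropic diffusion tensor D = D_T I + (D_L−D_T) f fᵀ along the local
fiber direction f, no-flux boundaries, and non-conducting fibrotic nodes.
D_L is calibrated by bisection so the plane-wave conduction velocity
matches a target.

Measurements: APD90 (time from max dV/dt to 90% repolarization), CV
(distance/ΔLAT), the restitution curve APD(DI) = y0 + A1(1 − e^(−DI/τ1))
with maximal slope Smax = (A1/τ1)e^(−DI_min/τ1), AF cycle length (mean
inter-activation interval), dominant frequency (3–15 Hz periodogram
peak), and phase singularities (±2π winding of the Hilbert phase) tracked
over time.  Ensembles are summarized with Student's/paired t-tests,
Cohen's d, and Fisher-exact termination-rate contrasts.

See `docs/methods.md` for conventions, numerical choices and desk-scale
caveats.

## Worked example

Paced APD90 of the two genotypes and the effect of a class III drug:

```python
from afvtrial import cellmodel, conditions

for genotype in ("wild_type", "pitx2_deficient"):
    sr = conditions.genotype_baseline(genotype, "SR")
    tr = cellmodel.pace_cell(sr, cycle_length=600.0, n_beats=10)
    apd = cellmodel.measure_apd90(*tr.last_beat())
    hi = conditions.apply_drug(sr, "amiodarone", "high")
    tr_hi = cellmodel.pace_cell(hi, cycle_length=600.0, n_beats=10)
    apd_hi = cellmodel.measure_apd90(*tr_hi.last_beat())
    print(f"{genotype}: APD90 {apd:.1f} ms -> {apd_hi:.1f} ms with "
          f"amiodarone high")
```

prints

```
wild_type: APD90 286.1 ms -> 396.4 ms with amiodarone high
pitx2_deficient: APD90 227.2 ms -> 369.1 ms with amiodarone high
```

— the deficient genotype has the shorter baseline action potential
(227 vs 286 ms, the AF-susceptible phenotype), and the potassium-channel
blocker prolongs both, the class III antiarrhythmic mechanism.

A small tissue case from the shell:

```sh
afvtrial substrate --seed 1 --out scratch/sub1      # synthetic map
afvtrial conditions validate                        # genotype-table checks
afvtrial simulate --genotype wild_type --rhythm AF --drug flecainide \
    --dose high --seed 1 --af-window-s 4 --out scratch/case.json
afvtrial trial --seeds 10 --out scratch/trial       # full grid; slow
```

`afvtrial trial` writes `table3_ephys.csv`, `table4_deltas.csv`,
`table5_termination.csv` and a per-case JSON archive from which
`afvtrial report` regenerates the tables bit-identically.

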