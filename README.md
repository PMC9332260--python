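# luxtherm

Thermal-stability analytics for bacterial luciferases — and for any enzyme
studied with the same toolbox of single-turnover kinetics, thermal
inactivation, differential scanning calorimetry (DSC) and molecular-dynamics
trajectory statistics.

Bacterial luciferases are heterodimeric flavin monooxygenases that emit
light while oxidizing FMNH⁻ and a long-chain aldehyde.  Because unbound
FMNH⁻ autoxidizes quickly, a stopped-flow assay gives a single catalytic
turnover: a "flash" of light that rises, peaks and decays.  Comparing a
"slow" (*Vibrio harveyi*) and a "fast" (*Photobacterium leiognathi*)
luciferase across temperatures — in buffer and in a 30 wt% (0.99 M) sucrose
solution — requires four quantitative layers, all implemented here:

1. **Flash kinetics** (`luxtherm.flashkin`) — from a trace *I(t)*: the peak
   intensity *I*<sub>max</sub>, the total light output
   *Q*\* = ∫ *I* d*t*, and the decay constant from a single-exponential fit
   *I* = *B* e<sup>−*k*<sub>decay</sub>*t*</sup> to the decay phase.
2. **Thermal inactivation** (`luxtherm.inactivation`) — remaining activity
   *R* = 100·*Q*\*/*Q*₀\*, segmentation of the time course into induction
   lag / exponential decay / late slow phase, the fit
   *R* = *A* e<sup>−*kt*</sup>, and the Arrhenius activation energy
   *E*<sub>a</sub> = −*R*<sub>gas</sub> · d ln *k* / d(1/*T*).
3. **DSC thermodynamics** (`luxtherm.dsc`) — excess heat capacity by
   subtraction of a progress-blended (sigmoid) baseline, then
   *T*<sub>m</sub>, the half-width Δ*T*<sub>1/2</sub>, the calorimetric
   enthalpy Δ*H*<sub>cal</sub> = ∫ *C*<sub>p</sub><sup>exc</sup> d*T*, and
   the peak asymmetry Δ*Q*₋/Δ*Q*₊.
4. **Trajectory statistics** (`luxtherm.trajstat`) — Kabsch superposition,
   backbone RMSD, radius of gyration, Shrake–Rupley SASA, per-residue RMSF
   and ΔRMSF = RMSF<sub>T</sub> − RMSF<sub>27</sub>, profile correlations,
   the minimum-distance distribution function (MDDF) of a cosolvent, and
   per-residue cosolvent density maps over 1.5–3.5 Å.

A fifth module, `luxtherm.synthgen`, generates every input the pipelines
consume — flash traces, activity courses, two-state thermograms, and
harmonic-fluctuation trajectories with optional cosolvent enrichment — from
known ground-truth parameters with explicit seeds, so every estimator can
be validated by parameter recovery.

## Worked example

```python
import numpy as np
import luxtherm as lx

# Arrhenius analysis of measured inactivation rate constants (1/min)
res = lx.arrhenius_fit([0.15, 0.71, 1.36, 1.63, 2.69], [45, 48, 50, 52, 55])
print(f"E_a = {res.E_a:.1f} +/- {res.stderr_Ea:.1f} kJ/mol  (n = {res.n_points})")

# rate recovery from a synthetic remaining-activity course (true k = 1.36)
p = lx.InactivationModelParams(k=1.36, t_lag=1.0, noise_sd=0.02,
                               times=np.arange(0.0, 4.001, 1/3), seed=42)
fit = lx.fit_inactivation(lx.gen_inactivation_series(p))
print(f"k = {fit.k:.3f} 1/min  (r2 = {fit.r2:.4f}, "
      f"{fit.induction_idx.size} induction points excluded)")

# DSC pipeline on a synthetic two-state thermogram (true T_m = 318.5 K,
# dH_cal = 997 kJ/mol, FWHM 4.2 K; sloping baselines, 1% peak noise)
dh_vh = lx.vant_hoff_from_fwhm(318.5, 4.2)
peak = 997.0 * dh_vh * 1e6 / (4 * 8.314 * 318.5**2) / 1000
tp = lx.ThermogramModelParams(T_m=318.5, dH_cal=997.0, dH_vH=dh_vh,
    native_baseline=(30.0, 0.05), denatured_baseline=(60.0, 0.08),
    noise_sd=0.01 * peak, T_grid=np.arange(290.0, 350.0001, 0.05), seed=7)
dp = lx.denaturation_params(lx.excess_heat_capacity(lx.gen_thermogram(tp)))
print(f"T_m = {dp.T_m:.2f} K, dT_1/2 = {dp.dT_half:.2f} K, "
      f"dH_cal = {dp.dH_cal:.0f} kJ/mol, dQ-/dQ+ = {dp.asymmetry:.2f}")

print(f"sucrose 30 wt% = {lx.sucrose_molarity(0.30):.2f} M")
```

prints

```
E_a = 241.6 +/- 46.2 kJ/mol  (n = 5)
k = 1.324 1/min  (r2 = 0.9999, 4 induction points excluded)
T_m = 318.48 K, dT_1/2 = 4.17 K, dH_cal = 992 kJ/mol, dQ-/dQ+ = 0.97
sucrose 30 wt% = 0.99 M
```

The activation energy of ~242 kJ/mol comes straight from the five printed
rate constants; the recovered k, T<sub>m</sub>, ΔT<sub>1/2</sub> and
ΔH<sub>cal</sub> sit within a few percent of the generator's ground truth,
which is what the noise level of the synthetic data permits.

## Command line

The same pipelines are exposed as a thin CLI named `tzk`:

```sh
tzk simulate flash --out trace.tsv --k-decay 0.32 --noise-sd 0
tzk flash trace.tsv
tzk simulate dsc --out tg.tsv --t-m 318.5 --dh-cal 997 --dt-half 4.2
tzk dsc tg.tsv
tzk inactivation arrhenius rates.tsv     # two columns: T_C, k_per_min
tzk traj rmsf trajectory.pdb --out rmsf.tsv
```

Each file-writing run leaves a `<out>.provenance.json` with the exact
parameters, seed and package version.

## Layout

```
src/luxtherm/
  synthgen.py      # seeded generators for every input type
  flashkin.py      # I_max, Q*, k_decay extraction
  inactivation.py  # R, phase segmentation, k fits, Arrhenius E_a
  dsc.py           # excess heat capacity, T_m, dT_1/2, dH_cal, asymmetry
  trajstat.py      # RMSD, R_g, SASA, RMSF/dRMSF, MDDF, density maps
  io.py, units.py  # delimited-text + PDB/XYZ readers/writers, lab units
  cli.py           # the tzk umbrella command
docs/methods.md    # models, assumptions, numerical choices, limitations
```
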