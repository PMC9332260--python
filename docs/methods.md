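# Methods

This note documents the models behind each pipeline, the numerical choices
that are not obvious from the code, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Flash kinetics

A single-turnover bioluminescence trace is summarized by three empirical
parameters: the peak intensity I_max (maximum sample, ties to the earliest),
the total light output Q* (trapezoidal integral, with negative noise samples
clipped to zero for integration only), and the decay constant k_decay from a
nonlinear least-squares fit of I = B·exp(−k_decay·t) to the decay phase.

The fit window runs from the first post-peak sample at or below 60% of the
peak to the last sample at or above 5% of the peak.  The lower cut removes
the detector floor.  The upper cut removes contamination by the rise phase:
the generator's two-exponential model shows that starting at 80% of peak
leaves a relative bias of ~2·10⁻³ on k_decay at a rise/decay rate ratio of
10, while starting at 60% leaves ~1.4·10⁻⁴ and costs nothing in precision on
noisy traces (median recovery error 0.4% at 2% noise either way).  Both
fractions are exposed as parameters.

The fit runs in the original intensity space rather than log space, so
near-zero tail samples (whose log-variance diverges) do not dominate; a
log-space line through the positive samples supplies the starting values.

## Thermal inactivation

Remaining activity is R = 100·Q*/Q₀* — the treated enzyme's light area as a
percentage of the untreated control.  A time course has up to three phases:

* **Induction lag** — early heat exposure from which the enzyme fully
  recovers on cooling; R stays near 100%.  The lag is the leading run of
  points with R ≥ 100 − tol (tol defaults to 5 percentage points).  Two
  robustness rules: a point inside the run also counts when it is within
  the tolerance of the running median of the lag so far (the 100% anchor is
  itself a noisy measurement), and a single below-threshold dip whose
  successor returns above threshold does not end the run.  A run consisting
  of the t = 0 point alone is not a lag: R(0) is 100 by construction, so a
  lone initial point means decay began immediately.
* **Exponential phase** — fit with R = A·exp(−k·t) on the original time
  axis with A free, mirroring the two-parameter form in which A absorbs the
  lag.  r² is reported on this segment.
* **Slow phase** — at the highest temperatures the course levels off at a
  nonzero floor, usually attributed to aggregation preventing refolding.
  These trailing points are excluded from the rate fit rather than modelled.
  Detection fits a provisional offset-exponential A·exp(−k·t) + c to the
  decay; a slow phase is called when the offset is statistically significant
  (> 3 standard errors) and non-negligible (> 1 percentage point), and the
  flagged points are the trailing ones where the offset exceeds the decaying
  component.  A residual-threshold change-point on a plain exponential fit
  was tried first and discarded: with a 10% floor, the floor contaminates
  nearly every post-lag point (at k = 1.36 min⁻¹ it already contributes 18%
  of R one sample after the lag), so any provisional single-exponential fit
  absorbs it and no change-point appears.  At least 3 trailing points are
  required to call a slow phase, and at least 3 points must remain before it.

Activation energies come from unweighted ordinary least squares of ln k on
1/T (T in kelvin, °C + 273.15), E_a = −slope·R_gas reported in kJ/mol with
the OLS standard error.  Replicate rates at one temperature are allowed; at
least two distinct temperatures are required.

Validated behaviour (2% multiplicative noise, 13 points, 1-min lag, 200
seeds per rate over the full measured rate range 0.02–2.69 min⁻¹): every
fit reaches r² > 0.96, median |bias| < 0.3%, worst-case ~6%.  The
fit-quality property is intrinsically about the exponential phase; the lag
rules above are what make it hold when a lag is present.

## DSC

The generator produces a two-state van't Hoff transition: with
K(T) = exp[(ΔH_vH/R)(1/T_m − 1/T)] and progress α = K/(1+K), the excess
term is C_exc = ΔH_cal·ΔH_vH·K / (R·T²·(1+K)²), whose integral equals
ΔH_cal; it sits on native/denatured baselines B_N and B_D (linear in T)
blended by α, plus optional Gaussian noise.  An optional skew term (linear
temperature dependence of ΔH_vH) can emulate the asymmetric peaks of
irreversible denaturation; it is off by default.  The helper
`vant_hoff_from_fwhm` inverts the half-maximum condition (K² − 6K + 1 = 0,
ln K = ±1.7627) to give the ΔH_vH that produces a requested full width at
half maximum: FWHM ≈ 3.5255·R·T_m²/ΔH_vH.

Baseline correction follows standard calorimetric practice: linear fits over
the outer 15% of the scan (both fractions configurable) seed B_N and B_D;
the subtracted baseline is (1−α̂)·B_N + α̂·B_D with α̂ the normalized
cumulative integral of the current excess curve, iterated to a fixed point
(relative-area tolerance 10⁻⁶).  The procedure then runs a second stage:
the transition is located from the quartile crossings of α̂ (steep-slope
points that noise barely moves), the exponential wings' e-folding length is
inferred from the quartile separation, and the baselines are refit over all
points more than 7.5 e-folds outside the transition.  The seed regions
alone would leave a long extrapolation lever arm — at 1% peak-height noise
it costs ~3% standard deviation on ΔH_cal — while extending the fit regions
without the e-fold guard lets the transition wings bias the baselines.
With the guard, the noise-free excess curve is recovered to ≤ 0.26% of peak
height and ΔH_cal to within 0.6%; at 1% peak noise ΔH_cal is recovered
within 1.2% (worst of 100 seeds).

Peak parameters: T_m is the vertex of a least-squares parabola through all
samples at ≥ 90% of the maximum (a 3-point parabola is unusable on a fine
grid — the second difference over 0.05 K is far below realistic noise;
the windowed fit gives a mean |error| of 0.017 K at 1% peak noise).
ΔT_1/2 is the full width at half maximum with linear interpolation on each
flank ("half-width" is read as FWHM, which reproduces the magnitude of
measured half-widths given the measured enthalpies).  ΔH_cal is the
trapezoidal integral of the corrected curve, and the asymmetry ΔQ₋/ΔQ₊
splits that same quadrature at T_m, so ΔQ₋ + ΔQ₊ = ΔH_cal exactly.

Molar conversion multiplies specific heat capacity (J K⁻¹ g⁻¹) by the
molecular weight; when the metadata gives no MW the luciferase heterodimer
value of 80,000 Da is used with a logged notice.  The partial specific
volume rides along in metadata but does not enter the excess computation.

## Trajectory statistics

Coordinates are in ångströms, residue ids 1-based as in PDB.  Backbone means
atom names N/CA/C/O; the Cα selection is the atom name CA.  Distances in a
cubic periodic box use the minimum-image convention; the mobile-loop
defaults from the two luciferases are residues 262–291 (*V. harveyi*) and
261–290 (*P. leiognathi*).

* **Superposition** — own Kabsch implementation (SVD of the weighted
  covariance, reflection branch corrected to det +1), cross-checked in the
  tests against a brute-force numerical minimization over rotation vectors.
* **RMSD** — each frame is superposed on the reference over the selection
  and the RMSD evaluated on the same selection; a tail-mean helper reports
  the equilibrated last fraction of the series.
* **RMSF** — frames are superposed on the running mean structure in two
  passes.  The second pass weights atoms by the inverse variance estimated
  in the first (with a 5% ridge), because unweighted superposition lets
  highly mobile atoms drag the fit and leak their fluctuation into rigid
  ones: on a 30-atom chain with 6-fold amplitude contrast, unweighted
  fitting misestimates the extreme atoms by up to 28%, weighted fitting by
  ≤ 8%, and on a 100-atom chain by ≤ 5%.  The residual is an end-of-chain
  effect of removing 6 rigid degrees of freedom and shrinks with system
  size.  ΔRMSF is the elementwise difference of two profiles on identical
  residue vectors (positive = more flexible); profile correlation is
  Pearson's r over an inclusive residue-id window applied to each profile
  independently, so homologous proteins with offset numbering compare
  position-by-position.
* **SASA** — Shrake–Rupley with a deterministic Fibonacci sphere lattice
  (default 256 points, refusing < 32), probe 1.4 Å, so results are
  bit-reproducible; validated against a dense random-sphere oracle to 2%.
* **MDDF** — per frame and cosolvent molecule, the minimum atom-pair
  distance to the solute selection is histogrammed (default 0.1 Å bins to
  r_max = 10 Å, refused beyond half the box edge).  Normalization divides
  by the expected count for the same number of molecules placed uniformly
  in the box, estimated per frame by seeded random insertion with 10-fold
  oversampling — minimum-distance shells of an irregular solute have no
  closed-form volume.  Uniform cosolvent therefore converges to 1, at the
  ~1/√(frames·molecules) rate of both counting processes.
* **Density maps** — entry (residue, bin) is the per-frame probability that
  at least one cosolvent molecule's minimum distance to that residue falls
  in the bin (default 0.25 Å bins over 1.5–3.5 Å).  Being a frequency, it
  is invariant to frame count.  "At least one molecule per frame" was
  chosen over raw counts because it matches an occupancy reading of
  appearance probability; with more than ~1 expected molecule per bin per
  frame the probability saturates and compresses contrast, so enrichment
  comparisons should be run at moderate cosolvent densities.

## Synthetic data

The generators emulate the statistical structure of the instrument and
simulation outputs, not their physics:

* Flash traces: I(t) = A·(e^(−k_decay·t) − e^(−k_rise·t)) plus additive
  Gaussian noise (fraction of peak).  The single-exponential rise is a
  modelling convenience — only the decay constant is a measured quantity;
  the rise shape merely reproduces the flash-like form.
* Activity courses: R = 100 during the lag, then
  (100 − plateau)·e^(−k·(t−t_lag)) + plateau, times multiplicative Gaussian
  noise — activity ratios carry relative error, and R(0) stays at 100.
  Lag durations of 0.5–8 min and a ~10% plateau reproduce the observed
  induction phases and the 50 °C aggregation floor.
* Thermograms: the two-state model above.  Real luciferase denaturation is
  calorimetrically irreversible; the equilibrium two-state form is the
  cleanest peak shape with known area and width, which is what the
  estimator validation needs.
* Trajectories: reference + isotropic Gaussian displacement with
  per-coordinate sd RMSF_target/√3 (so sampled RMSF converges to the
  target), optionally composed with a uniform random rotation and a
  translation; cosolvent particles are points placed uniformly in the box
  except, with probability (enrichment − 1)·V_shell/V_box per enriched
  residue, uniformly in that residue's 1.5–3.5 Å shell — giving shell
  counts enriched by exactly the requested factor in expectation.

Noise defaults are 2% (relative) for kinetic data; the measurements behind
the printed tables do not state their noise levels, so these are plausible
instrument magnitudes, not calibrated ones.  Every generator draws all its
randomness from one explicit integer seed.

What passing recovery tests shows — and does not: the estimators are
unbiased and precise on data whose noise is Gaussian, uncorrelated and of
stated magnitude, whose decays are truly single-exponential, and whose
trajectories are harmonic about a fixed reference.  Real traces have
correlated detector noise and mixing artifacts, real inactivation may be
multi-phasic, real DSC peaks are kinetically skewed, and real MD has
anharmonic, correlated motions; none of that is exercised here.

## Problem sizes

The validation suite runs at deliberately modest scale: kinetic recovery
uses 13-point courses and 200-seed replicate sweeps; DSC uses 1201-point
scans (0.05 K steps over 290–350 K) and 100-seed sweeps; trajectory
statistics use 10–100-atom chains with 500–2000 frames and ≤ 200 cosolvent
particles.  These sizes put sampling error comfortably below the tested
tolerances while keeping the whole suite around ten seconds.

## Limitations

* No mechanistic rate constants (dark decay of the peroxyflavin
  intermediate, aldehyde binding) are estimated — k_decay is empirical.
* No multi-exponential decay decomposition; no deconvolution of DSC peaks
  into multiple transitions; no kinetic (scan-rate-dependent) irreversible
  DSC models; ΔH_vH is a generator parameter, never fitted to data.
* Transition-state parameters beyond E_a (ΔH‡, ΔS‡) are not computed.
* The trajectory reader handles multi-MODEL PDB and multi-frame XYZ only;
  binary formats (XTC/DCD) are out of scope, as is running MD itself.
* Solution viscosity is not modelled; sucrose concentration enters only
  through the weight-fraction-to-molarity conversion (default solution
  density 1.127 g/mL at 20 °C).
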