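# Methods

## The measurement model behind the simulator

A colloidal-SERS spectrum of a dye mixture is modelled on a fixed
Raman-shift axis (400–2000 cm⁻¹ at 2 cm⁻¹ spacing, 801 channels — the
stated acquisition range; the spacing is a desk-scale choice) as

```
s = (1 + ε) · ( Σ_j g_j · r_j(c_j) · P_j + M ) + d + e
```

- `P_j` — unit-scale component signature of dye j: a sum of Lorentzian
  bands (HWHM 5–8 cm⁻¹; Gaussian shapes available). Sudan I uses the
  band positions reported for that dye (722, 753, 1000, 1198, 1258,
  1506 cm⁻¹). **Sudan II–IV and the matrix band sets are synthetic**:
  no positions are printed for them, so the library ships invented,
  mutually distinguishable sets with partial overlap. They are plumbing
  for testing the pipeline, not literature assignments.
- `M` — matrix background (aggregated gold colloid, citrate, acetonitrile):
  broad bands (HWHM 25–50 cm⁻¹) whose integrated intensity dominates each
  spectrum's variance, as the citrate/solvent background does in real
  colloidal SERS of dilute analytes. This dominance is also what makes
  SNV-normalized intensities an approximately linear function of
  concentration (see below).
- `r_j(c) = c / (1 + c/c_sat_j)` — Langmuir-type adsorption response;
  `c_sat = ∞` (exactly linear) by default, a finite-`c_sat` library is
  provided to emulate the adsorption-competition regime that degrades
  quantification of the larger dyes.
- `g_j` — response gain (intensity per M), set so the strongest band of
  each dye reaches roughly half the matrix apex at the top of its linear
  range (Sudan I 0.048 mM, II 0.036 mM, III 0.028 mM, IV 0.026 mM).
- `ε ~ N(0, 0.02)` per replicate — spectrum-level intensity variability;
  `e ~ N(0, 0.01)` per channel — shot/detector noise at 1% of a unit band
  apex; `d` — a random cubic over the axis scaled to amplitude 0.05,
  emulating the smooth baseline that AsLS must remove. Three technical
  replicates per sample, as in the reference acquisition protocol.

These defaults are the package's study conditions; the seeded generator
reproduces a data set bit-exactly from its configuration.

What the simulator does **not** emulate: electromagnetic-enhancement
physics, nanoparticle aggregation kinetics, competitive displacement
between dyes (beyond the scalar Langmuir response), wavelength-dependent
detector response, cosmic-ray spikes. Passing tests therefore demonstrate
the correctness and statistical behaviour of the *pipeline*, not
instrument-level performance on real extracts — the published figures of
merit for real spectra are not reproducible from synthetic data, and no
test asserts them.

## Preprocessing

Two chains, as in the reference workflow:

- **PCA branch**: AsLS baseline correction → Savitzky–Golay smoothing →
  vector (unit-L2) normalization.
- **Calibration branch**: SNV only (per-spectrum centering and unit-SD
  scaling, n−1 denominator).

AsLS minimizes `Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²` with `w_i = p` above the
baseline and `1 − p` below, re-estimated for 10 iterations; defaults
λ = 1e5, p = 0.001 (standard Eilers–Boelens settings — the source
workflow names the method but not its parameters). The sparse banded
solve is contractually within 1e-8 of a dense solve, and at p = 0.5 the
result is the symmetric Whittaker smoother. Savitzky–Golay defaults are
window 9, order 3 (a common Raman choice); edges use a polynomial fit on
the truncated window. Edge channels are not trimmed.

Because SNV rescales each spectrum by its own SD, a strictly linear
response in raw intensities becomes a rational function of concentration
after SNV. With the matrix dominating the per-spectrum SD the curvature
is small (relative nonlinearity ~0.2% over the simplex range with the
default library), which is why the calibration branch still reaches
Q² > 0.99; an exactly-zero LOD is only observable on raw noiseless
spectra, where the calibration map is exactly affine.

## PCA

SVD of the column-mean-centered matrix; no channel scaling (spectra are
already normalized upstream). Explained variance is reported as a
fraction of total centered variance. Sign convention: the largest-|value|
channel of each loading is made positive, so score plots are reproducible
run to run. On a noiseless, preprocessed dilution series PC1 scores are
strictly monotone in concentration — the in-silico analogue of the
dilution trend seen in exploratory score plots.

## PLS calibration

NIPALS extraction on mean-centered X and Y (no autoscaling: SNV already
standardizes spectra, and leaving Y in molar units keeps every RMSE in
M). After each component X and Y are deflated by the X-score; the fitted
model collapses to `Ŷ = (X − x̄) B + ȳ` with
`B = W (PᵀW)⁻¹ Qᵀ`. PLS1 and PLS2 share the code path; a single-column
Y reproduces PLS1 exactly. Inner-loop convergence: score change below
1e-12 or 500 iterations; component extraction stops early (logged) when
the residual X or Y variance reaches the machine-precision floor, and at
most min(15, n−1) components are considered anywhere. At full rank the
NIPALS solution equals the pseudoinverse least-squares fit — this
equivalence, and agreement with an independent implementation, are tests,
not assumptions.

Figures of merit: `Q² = 1 − Σ(y − ŷ)² / Σ(y − ȳ_train)²` against the
*training-set* mean, computed on held-out predictions (on training data
the same quantity is reported as R²); RMSE in M. A constant reference
equal to the center yields NaN with a warning.

## Validation

**Double (nested) CV** for dilution series: outer folds are the k = 7
concentration levels, so all three replicates of a level are held out
together; the inner (k−1)-fold CV on each outer training set picks the
component count minimizing pooled inner RMSECV (ties go to fewer
components); outer held-out predictions are pooled into one Q²/RMSECV per
run (per-fold averaging available by flag). Pooled metrics use the grand
mean as center, matching how a single predicted-vs-known plot is read.

**Bootstrap out-of-bag** for mixtures: each iteration draws n sample ids
with replacement (the training multiset — duplicated draws enter the fit
with their multiplicity via row replication), out-of-bag ids form the
test set, and an empty bag is redrawn (logged). The inner k-fold on the
training ids uses k = min(distinct training ids, 7), keeping the inner
folds comparable to the simplex k. Reported per iteration: training R²,
inner RMSECV at the selected component count, out-of-bag Q² and RMSEP;
summaries are means ± SD across iterations plus per-sample prediction
mean/SD for predicted-vs-known plots. Resampling is at the *sample* level
throughout — technical replicates never straddle a split — an
anti-leakage decision the source protocol leaves unstated. The reference
protocol uses 1000 iterations per PLS1 model and 10,000 for PLS2 (those
remain the `BootstrapConfig` defaults); the test suite and the acceptance
script run 200, which is enough to stabilize the Q² means they assert.

R² is reported as training-fold linearity and labelled as such; whether a
training or cross-validated R² was intended in the reference tables is
ambiguous, so the choice is documented here rather than hidden.

## Limit of detection

Pseudo-univariate estimate from calibration output: ordinary least
squares of cross-validated predicted vs nominal concentration, residual
SD `s_res = √(Σr²/(n−2))`, and `LOD = 3.3 · s_res / b`. The 3.3
multiplier is the ICH-style α = β = 5% convention; 3 is available by
flag. The named literature method admits several variants (blank-based,
different multipliers); this regression-on-CV-predictions variant is a
deliberate, documented choice, and predictions always come from held-out
folds — training fits would understate `s_res`. A non-positive slope
flags the estimate invalid rather than returning a negative LOD.

## Latin hypercube design

Each column partitions [0,1] into m equal strata, draws one uniform point
per stratum and permutes the strata independently — the defining
one-point-per-stratum property is hard-asserted in tests. Fractions are
optionally snapped to a 21-level grid (5% steps, ties round up, never
moving a point more than half a step) and scaled so 100% maps to each
dye's linear-range upper bound; 0% rows are genuine absences. The
reference design's explicit 90-mixture table lives in an appendix that is
not machine-readable here, so the generator regenerates an equivalent
design (m = 90, p = 4, 21 levels) instead of hard-coding it. No maximin
or orthogonal LHS variants are attempted.

## Numerical and reproducibility choices

- One master seed per pipeline run; stage seeds derive from
  `numpy.random.SeedSequence(master)` and stay below 2³¹.
- CSV numerics are written with 17 significant digits and parsed in
  round-trip mode, so write→read is bit-exact and re-running a config
  reproduces every output file.
- Degenerate inputs fail loudly: zero-variance spectra in SNV, all-zero
  vectors in normalization, non-finite AsLS input, negative design
  concentrations, component counts beyond `min(n−1, p)`.
- Problem sizes used by the shipped tests and the acceptance script —
  7 levels × 3 replicates for dilution series, 90 mixtures × 3 replicates,
  200 bootstrap iterations, 100-seed LHS sweeps, 2000-draw out-of-bag
  simulations — are the package's desk-scale defaults for a reproducible
  demonstration of the method's statistical behaviour.

## Known limitations

- The PLS1-vs-PLS2 accuracy ordering seen on real multiplexed data (PLS1
  slightly ahead) is only softly reproduced: under the clean synthetic
  conditions both modes sit above Q² 0.99 and the gap is within noise.
  The suite checks PLS1 is not materially worse, not that it wins.
- With only 7 concentration levels, a permutation null over levels
  retains a few near-rank-monotone permutations, so permutation tests on
  the dilution series destroy predictivity for the typical permutation
  (median Q² ≪ 0) but not for every seed.
- LOD estimates inherit the nonlinearity left by SNV; on noiseless SNV
  data the LOD is small but not exactly zero.
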