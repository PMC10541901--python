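# Methods

This note documents the models implemented in `mmpol`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical choices a maintainer should know about.

## Optical model and instrument forward simulation

All optics are incoherent Stokes–Müller calculus in the (I, Q, U, V)
basis. Angles are radians, counterclockwise from horizontal looking
toward the source; rotating an element by θ rotates the (Q, U) plane by
2θ. Element constructors (polarizer, linear retarder, diagonal
depolarizer, linear diattenuator) are textbook closed forms; only forward
composition is used — the package performs no Müller-matrix
decomposition, because the classification approach under study consumes
raw matrix values.

The simulated polarimeter is a dual rotating retarder: PSG = fixed
polarizer at 0° + quarter-wave plate at kΔ; PSA = quarter-wave plate at
qkΔ + fixed polarizer at 0°; a scalar detector reads total intensity.
Defaults: q = 5, N = 36 measurements, Δ = π/N (half revolution of the PSG
plate per sequence), ideal quarter-wave retardance at every wavelength
(per-wavelength overrides available), five bands at 450, 470, 500, 540,
625 nm. The 5:1 ratio is the canonical choice making all 16 Müller
elements identifiable; the design matrix built from rows a_k ⊗ s_k has
rank 16 and condition number ≈ 13 at these defaults. Identifiability is
checked at construction: degenerate configurations (e.g. both retardances
zero) raise an error naming the offending parameters. Note that exactly
N = 16 measurements at Δ = π/16 alias (rank 14); the 16-measurement
square system is only invertible at a finer step such as Δ = π/36, which
is what the equivalence-with-direct-inversion check uses.

Noise model: Gaussian shot noise with variance equal to the expected
count (the large-count Poisson limit), plus additive Gaussian read noise
(default sd 2 counts), then clipping at the detector full scale (default
65535 counts, with source intensity 20000 counts and unit gain so
ordinary tissue pixels sit far from saturation). Frames that clip are
flagged; a pixel with *any* clipped frame across all steps and
wavelengths is excluded from analysis — the conservative reading of
"saturated pixels removed".

Reconstruction is linear least squares through a pseudo-inverse
precomputed once per configuration — the maximum-likelihood estimate
under homoscedastic Gaussian noise, exact (≈1e-15 Frobenius) on noiseless
data, and with estimator sd verified to shrink as 1/√R when averaging R
acquisitions. Fourier-coefficient demodulation would be equivalent for
noiseless data; least squares was chosen because it is exact for any
identifiable schedule, not just harmonic ones.

## Synthetic cohorts

Each phantom pixel is composed in Lu–Chipman order,
M = M₀₀ · M_depol(a,b,c) · M_ret(δ, θ) · M_diat(d, axis), with parameters
drawn per pixel from a per-class spec. This order is a modeling
convention for generating realistic, physically realizable matrices (all
draws are screened by the physicality gate; out-of-bound parameter draws
are redrawn, at most 100 rounds), not a claim about pancreas
microstructure.

Default class parameters (free choices — the study reports no
quantitative polarimetric contrast between its classes; these were chosen
once to produce a strong but imperfect pixel-level separation in the
regime the study reports, AUC > 0.9 at default instrument noise):

| parameter (at 625 nm) | normal | abnormal |
| --- | --- | --- |
| retardance mean ± sd (rad) | 0.60 ± 0.10 | 1.20 ± 0.15 |
| fast axis mean ± spread (rad) | 0 ± 0.30 | π/6 ± 0.40 |
| depolarization (a, b, c) ± sd | (0.85, 0.85, 0.75) ± 0.04 | (0.60, 0.60, 0.48) ± 0.05 |
| diattenuation mean ± sd | 0.05 ± 0.02 | 0.12 ± 0.03 |
| reflectance M₀₀ mean ± sd | 0.55 ± 0.05 | 0.45 ± 0.05 |

Wavelength dependence: retardance scales as λ_ref/λ and depolarization
factors as (λ/λ_ref)^0.3 (shorter wavelengths depolarize more) from the
625 nm reference — plausible dispersion that makes the five bands carry
distinct but correlated information. One pixel draws its base parameters
once and the dispersion maps them across bands, so per-pixel spectra are
coherent.

Cohort structure mirrors the emulated study's bookkeeping: default 11
patients and 15 samples, 2 mixed (both tissue regions), 7 all-normal, 6
all-abnormal — so 9 samples contain normal and 8 contain abnormal
tissue. Mixed-sample geometry is a smoothed random field thresholded at
its median; an unlabeled band (default 3 px each side of the region
boundary) mimics annotators only trusting uniform regions. Per-patient
additive offsets on retardance, fast axis, depolarization and reflectance
(scaled from `patient_effect_sd`, default 0.08) are shared by all of a
patient's pixels, inducing the intra-patient correlation that motivates
patient-wise fold splitting. A configurable hotspot fraction boosts M₀₀
~50× at random pixels to exercise detector saturation.
`intensity_matched=True` gives the abnormal class the normal class's M₀₀
distribution (offsets shared), removing the intensity class signal by
construction — the head-to-head condition isolating the value of
polarimetric information. `corrupt_registration` translates a label mask
while leaving optical data in place, with shifted-in pixels unlabeled,
emulating histology-to-polarimetry registration error.

What the phantoms do **not** emulate: radiative transfer in turbid
tissue, speckle, spatial texture within a region (pixels are i.i.d.
given patient and class), instrument misalignment or calibration error,
acquisition drift, and real pancreas microanatomy. Passing tests
therefore show the pipeline is correct and that the protocol behaves as
designed under known contrasts; they do not certify clinical
performance.

## Features and classifier

The pol representation normalizes each 4×4 matrix by 1/M₀₀, drops the
first element (now identically 1), flattens row-major and concatenates
the five wavelengths in ascending nm: 15 × 5 = 75 values, invariant to
any positive per-pixel gain. The no-pol representation is M₀₀ per
wavelength (5 values), which scales with gain — the structural reason the
two can diverge. No feature standardization is applied by default (an
optional train-fold-only z-scoring exists). Feature tables keep one row
per annotated, valid pixel with patient/sample identifiers.

The classifier is a single-hidden-layer MLP: 64 ReLU units, one logistic
output for the abnormal-class probability, binary cross-entropy, Adam at
learning rate 10⁻⁵, ten epochs of seed-shuffled mini-batches, no
regularization or early stopping. It is written directly in numpy so
training is bit-for-bit reproducible under a fixed seed and weights
serialize to JSON; it also implements the scikit-learn estimator
protocol.

Two scale choices matter at desk-size cohorts and are deliberate:

* **Batch size 32.** At the emulated study's scale (~4·10⁵ training
  pixels) ten epochs mean ~15k optimizer steps; a desk-scale cohort
  (~10⁴ pixels) at batch 256 would take only ~300 steps, which at
  learning rate 10⁻⁵ cannot move the network meaningfully. Batch 32
  restores step-count parity. The batch size is configurable.
* **Zero-initialized output head.** Hidden weights are Glorot-uniform
  (seed-controlled); the output layer starts at zero, so the initial
  logit is 0 (probability 0.5) and the pixel-score direction is entirely
  learned rather than inherited from a random projection. With a random
  head and this few steps, held-out ranking is dominated by
  initialization noise.

## Evaluation protocol

Patients are shuffled by seed and dealt round-robin into k = 4 folds, so
fold patient-counts differ by at most one and every sample of a patient
shares a fold; the train/test patient intersection is asserted empty on
every run. Per fold: pixel ROC and AUC (abnormal positive; AUC equals the
Mann–Whitney pairwise probability, ties ½), plus sensitivity,
specificity, type I and type II rates at the fixed threshold 0.43
(score ≥ threshold ⇒ abnormal; the boundary is inclusive by convention).
Specimen-level: a sample's prediction is the p-th percentile (linear
interpolation between order statistics; nearest-rank available behind a
flag) of its pixel scores, for every integer p in 50…99; the specimen
truth is abnormal iff any annotated pixel is abnormal; folds whose test
split contains a single specimen class skip specimen AUC with a logged
warning. Reports carry per-fold values, mean ± sd across folds, and a
pooled-score ROC separately (how the study averaged ROC across folds is
not stated). Report JSON is canonical (sorted keys), so identical seeds
reproduce byte-identical files.

The misregistration experiment trains one model on clean training
patients and re-measures held-out pixel AUC after shifting the test
annotations by 0, 3, 6 px. It uses a 1 px annotation-trust border rather
than the default 3 px: a border as wide as the shift absorbs the
corruption entirely (the pixels a small shift would mislabel are exactly
the ones left unlabeled), whereas tight annotations expose the
monotone AUC decay that misregistration causes.

## Orchestration and reproducibility

A single `RunConfig` (YAML-serializable) nests the instrument, cohort,
training and evaluation configs; every protocol constant (wavelengths,
64 hidden units, lr 10⁻⁵, 10 epochs, k = 4, threshold 0.43, percentiles
50–99) is a defaulted, overridable field. One global seed fans out to
each stage via `derive_seed(seed, stage_name)` (SHA-256, < 2³¹), so
stages are independently reproducible and a rerun regenerates
byte-identical evaluation reports. The bundled experiment sizes (8
patients × 12 mixed 32×32 samples for the matched comparison; 6 × 8 for
the misregistration sweep) are the package's default desk-scale study
conditions; results quoted in the README come from exactly these
configurations.

## Known limitations

* Effect sizes between phantom classes are free parameters; the package
  reproduces the *structure* of the emulated study (counts, protocol,
  pol-vs-no-pol contrast, misregistration failure mode), not its
  clinical AUC values, whose data is unavailable.
* The reflection geometry of a real instrument may impose sign
  conventions on measured matrices; the simulator treats the sample as
  an abstract Müller matrix.
* The simulator assumes a stable source and perfectly aligned ideal
  elements; no calibration procedure is modeled.
* Specimen-level AUC is undefined in folds with single-class specimens,
  which occurs readily in small demo cohorts (logged, reported as null).
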