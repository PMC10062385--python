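# Methods

This note documents the models, the synthetic data the pipeline is
validated on, and the numerical choices, in the order the data flows.

## Synthetic cohort model

The generator emulates a single-point fibre-probe Raman study of excised
breast tissue in the fingerprint region. The axis spans 600–1800 cm⁻¹ at
1.8 cm⁻¹ spacing (the native spectral resolution of a typical
high-sensitivity dispersive system; the exact acquisition range of such
probes varies, and this span covers all registry bands with margin).

**Signal model.** A tissue class's Raman signature is a sum of Gaussian
bands (Lorentzian available by flag) from a twelve-band registry: 760,
785, 940, 1004, 1129, 1159, 1176, 1208, 1246, 1266, 1302, 1600 cm⁻¹, with
FWHM 10–14 cm⁻¹. Relative amplitudes per class encode the standard
biomolecular contrasts: cancer strongest at the 1004 cm⁻¹ phenylalanine
ring-breathing band (normal intermediate, pure fat exactly zero — adipose
tissue contains no phenylalanine), normal dominated by the 940 cm⁻¹
collagen C–C stretch, fat by the 1129 and 1302 cm⁻¹ lipid acyl bands. The
exact ratios are free parameters of the generator; the defaults give class
contrasts of roughly 1.5–2× at the discriminative bands, consistent with
clearly separated per-class quartiles. Two optional extra lipid bands
(1440, 1655 cm⁻¹) add visual realism to fat spectra and are off by
default — they are not part of the emulated study conditions.

**Acquisition model.** One acquisition is N repeat exposures (default 10)
plus ≥ 1 dark frame. Each repeat is
`(Raman amplitude × signature × effects + baseline) + dark offset + noise`.
The acquisition protocol adjusts exposure time (0.1–4 s) to hit a target
detector intensity, so amplitudes are parameterized in detector counts
directly: the photon rate is `target/exposure` and the product with
exposure is the configured count level regardless of the drawn exposure.
Defaults: Raman peak scale 500 counts, baseline scale 5000 counts
(autofluorescence dominates the raw signal, as in tissue), dark offset
100 counts, additive Gaussian read noise of 50 counts per repeat
(shot-noise-free; the additive model is the simplest one that reproduces
the √N averaging gain the accumulation protocol exists for). The baseline
is a broad exponential decay plus a low-order polynomial with randomized
coefficients — smooth, structureless, and much larger than the signal.

**Random effects.** Each patient carries one multiplicative factor per
band (lognormal-ish, sd 10 %), shared by all of that patient's
measurements; each measurement adds a further 5 % band-level jitter. This
creates the within-patient correlation that makes patient-grouped
cross-validation matter.

**Planted failure modes.** The default cohort has 388 measurements from
20 patients: 238 clean (87 cancer / 58 normal / 93 fat by composition
draw), 58 noise-swamped acquisitions (zero Raman amplitude, 20× noise —
destined to fail the quality gate), 58 compositions that meet no labeling
threshold, and 34 label mismatches (28 fat signatures carried by
cancer/normal composition records, 6 protein signatures under fat
records), emulating spatial-registration errors between probe positions
and stained sections. Composition percentages are drawn so that every
non-planted record satisfies exactly one threshold.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: detector physics beyond offset + Gaussian noise
(no shot noise by default, no cosmic rays, no saturation), instrument
drift, water/quartz/substrate contributions, biochemical variability
beyond band-amplitude scaling (no peak shifts or width changes between
classes), and the true unknown effect sizes of patient tissue. The
near-perfect synthetic AUCs say the machinery is correct, not that real
margins classify this well.

## Preprocessing

Steps run strictly in order: averaging → dark subtraction → response
correction → calibration/resampling → baseline removal → SNV. Each output
carries a stage tag and per-step provenance.

- **Response correction** divides by measured/certified of a luminescence
  standard on the same axis; a response below 10⁻³ of its median aborts
  rather than amplifying a dead spectral region.
- **Calibration** detects polycarbonate peaks (prominence ≥ 10 % of range,
  parabolic sub-sample refinement), matches them to the reference table
  within 15 cm⁻¹, and fits a degree-1 polynomial (degree 2 optional)
  mapping observed → true wavenumber; ≥ 3 matches and a strictly
  increasing map are required. The spectrum is then linearly interpolated
  onto a uniform grid at 1.8 cm⁻¹ — the native resolution. Two deliberate
  choices here: resampling *finer* than the detector (e.g. 1 cm⁻¹) would
  correlate neighbouring noise samples and inflate any smoothness-based
  quality score, and the grid is anchored at the first calibrated sample
  so that for a near-identity map the nodes coincide with the original
  samples and interpolation does not mix noise.
- **BubbleFill.** A quartic polynomial trend is removed first and counted
  as part of the baseline: autofluorescence decays (further bent by the
  response correction) are strongly curved, and circles of bounded radius
  systematically under-track a steep convex slope, while a degree-4
  polynomial over a 1200 cm⁻¹ span cannot imprint anything at Raman-band
  scale. The detrended spectrum is scaled to a square pixel aspect
  (detrended range ↔ number of samples) so circle geometry is meaningful;
  bubbles are grown per span (half-bubbles of doubled radius at the two
  spectrum edges), each lifted until it touches the data, the touch point
  splits the span, and spans narrower than `min_bubble_width`
  (default 50 cm⁻¹, several times any tissue band width) end the
  recursion. The envelope plus trend, smoothed by a moving average of
  width `min_bubble_width/4`, is the baseline; the Raman component is
  defined as input − baseline, so the decomposition is exact by
  construction. One pass; no outer iteration.
- **SNV** uses the sample (n − 1) standard deviation; negative residuals
  after baseline removal are kept, not clipped. A constant spectrum is an
  error.

## Quality factor

qf = 1 − ‖x − smooth(x)‖² / ‖x − x̄‖² on the SNV spectrum, with a fixed
Savitzky–Golay smoother (window 9 samples ≈ 16 cm⁻¹, order 3), clipped to
[0, 1]. Tissue bands are wide enough for the smoother to follow (residual
≈ 0) while white noise leaves ≈ 75 % of its energy in the residual, so
noise-dominated spectra score ≈ 0.25 and clean tissue spectra > 0.9. The
published quality metric this reconstructs is not public; this form was
chosen because it is bounded, affine-invariant (inheriting SNV
invariance), and monotone in SNR. The gate excludes qf strictly below 0.6;
a spectrum exactly at 0.6 is kept.

## Labeling, screen, ledger

Labels from composition percentages, checked in the fixed order
cancer ≥ 80 % → normal ≥ 80 % → fat ≥ 70 % (all inclusive; the order only
matters for degenerate inputs whose percentages exceed 100 in total).
Exclusions apply in the order quality → no-category → signature mismatch.
The mismatch screen trains a fat-vs-rest linear SVM (balanced costs,
C = 1) on all post-category survivors — adipose spectra are so distinct
from protein-rich tissue that a ~12 % minority of mislabeled records does
not move the boundary — and flags records whose predicted fat status
contradicts their label. The ledger conserves counts by construction and
is validated on every run.

## Band features and sparse selection

Features are mean SNV intensities over registry band centres ± 5 cm⁻¹
(about three resolution elements; a per-bin mode exists for fidelity
experiments). Selection fits L1-penalized linear SVMs (standardized
features, balanced class weights) along a 30-point logarithmic penalty
path C ∈ [10⁻³, 10]. The |weight| is the relevance score, but two
hinge-loss pathologies make any single path point unreliable: at strong
penalty the fit concentrates weight on the most efficient member of a
correlated band group (dropping weaker genuinely-informative bands), and
at weak penalty it assigns small weights to bands that merely fit noise or
patient-level confounding. The rule therefore takes **candidacy and
ranking from the whole path** (any band whose weight reaches 5 % of the
largest |weight| at some path point, ranked by mean |weight| along the
path, ties toward the lower wavenumber) and **gates retention on
patient-level evidence**: a Welch test on patient-by-class mean
intensities, Bonferroni-corrected at α = 0.01. Patient means are the
correct test unit because measurements within a patient share random
effects; a band whose apparent relevance is carried by a few patients does
not survive. If nothing is significant (label-shuffled data), the single
top-ranked candidate is retained with a warning so downstream training
stays defined. The retained set never exceeds nine bands.

The planted-recovery validation plants class differences at exactly one
model's band set *in feature space* (two unimodal classes, registry
amplitudes at planted bands, class-midpoint amplitudes elsewhere, the
usual patient/measurement effects; 28 patients × 10 measurements, close
to the 238-measurement scale). Planting in raw spectra cannot confine
differences to chosen bands: SNV normalization couples every band to the
total intensity, so all bands become weakly class-informative and an
exact-recovery test would be testing a false premise. End-to-end,
generator-planted cohorts the retained set *contains* the planted bands.

## Classification and reporting

Per dichotomy: class-weighted linear SVM, minority-class cost
γ × (inverse class frequency) with γ ∈ {1, 2, 5, 10} and
C ∈ [10⁻³, 1] (7 log-spaced points), tuned by grid search under five-fold
patient-grouped CV (patients shuffled by seed, folds asserted disjoint at
every grid point). The mean held-out fold AUC selects the winning grid
point; its pooled held-out posteriors form the reported ROC (per-fold
accuracies are also emitted). Posteriors come from a Platt-style sigmoid
of the decision value, fitted on the training folds **with the same class
costs as the SVM** so the posterior-0.5 boundary honours the minority
weighting — with an unweighted sigmoid, increasing γ would not increase
minority recall.

The ROC sweeps every distinct posterior plus {0, 1} as threshold λ
(positive when p ≥ λ); the trapezoidal AUC equals the pairwise
concordance probability with ties counted ½ (asserted to 10⁻¹⁰ against
brute force in tests). The operating point minimizes
√((1 − specificity)² + (1 − sensitivity)²), ties broken toward higher
sensitivity — in margin assessment a missed positive margin is the
costlier error — and its metrics are recomputed from the confusion matrix
at λ*.

**Reduced-accumulation study.** Acquisitions are truncated to their first
N repeats (N = 10 reproduces the default run bit for bit) and the entire
dataset build and modeling repeats per N. The high-noise validation runs
at 250 counts of per-shot noise (single-shot SNR ≈ 1 against the
500-count Raman peaks, the regime where accumulation averaging is the
point) on a 12-patient × 12-measurement cohort, with the quality gate
disabled so that the same measurement set is compared across N — with the
gate active, low-N exclusions would confound the SNR effect with cohort
composition.

## Dosimetry

Average irradiance = power / (π(d/2)²) with unit conversion; the skin MPE
implements only the continuous-exposure branch (duration > 10 s,
700–1050 nm): MPE = 0.2 · C_A W/cm² with C_A = 10^(2(λ−700)/1000). The
short-exposure branch follows a different rule with ambiguous published
values and is rejected rather than guessed.

## Problem sizes and determinism

Default validation sizes: 388-acquisition cohorts for ledger and model
checks, 280-measurement feature cohorts × 20 seeds for planted recovery,
10 seeds for the end-to-end AUC and accumulation checks — sizes chosen to
match the emulated study's scale while keeping the full suite fast.
Every stochastic component draws from a `numpy` Generator seeded from the
run seed; identical (config, seed) reproduce cohorts, reports, and
checksums byte for byte.

## Known limitations

- The quality factor and BubbleFill parameterizations are reconstructions
  of unpublished algorithms; contracts (bounds, monotonicity, exact
  decomposition) are tested, equivalence to the originals cannot be.
- The band-selection evidence guard assumes ≥ 2 patients per class; with
  fewer it degrades to a measurement-level test that cannot control
  patient confounding.
- Linear SVMs only; no nonlinear kernels, no three-way classification.
- Synthetic accuracies are analogues, not reproductions, of any clinical
  figure.
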