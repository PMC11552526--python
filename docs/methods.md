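# Methods

This note documents the models and procedures the package implements, the
conventions it fixes where several were admissible, the synthetic data it
uses to validate itself, and what the passing tests do and do not establish.

## Data model and preprocessing

One measurement block is a channels x time matrix of detector voltages for a
(subject, breast side, wavelength) triple; channels are source-detector
pairs indexed source-major (`r = source * n_detectors + detector`, detector
fastest).  All indexing is 0-based with half-open ranges.  A subject record
holds the four blocks of {left, right} x {760, 830 nm}; a cohort is an
ordered list of records sharing block dimensions and a frame rate (default
1.8 Hz).

Preprocessing is deliberately minimal: blocks are truncated to a fixed
number of leading resting-state frames (default 400) so feature vectors are
commensurate, and may be restricted to channel subsets induced by sparse
optode geometries.  No filtering, detrending or channel pruning is applied —
the pipeline's premise is to hand the classifier data as raw as possible.

The on-disk cohort container is a directory with a `manifest.json` (schema
version, grid dimensions, frame count and rate, ordered subject list with
label and laterality) plus one matrix file per block, `.npy` or `.csv`.
Round-trips are bit-exact for `.npy`.  An adapter hook for the public
deposition of the clinical study data exists as a documented stub; nothing
in the package or its tests requires the clinical data.

## Normalization

Four per-block normalizations: relative change `x/μ`, z-score `(x−μ)/σ`,
zero-centering `x−μ`, robust `(x−median)/(p75−p25)`.  Statistics are always
pooled over all entries of *one* block — never across subjects or sides —
because continuous-wave readings are only meaningful relative to their own
measurement.  Conventions fixed here (the source analyses leave them open):
standard deviation uses the population (divide-by-N) form, and quantiles use
linear interpolation between order statistics with quantile `q` at
fractional rank `q·(N−1)`.  Any consistent choice only rescales features;
consistency is what the SVM requires.  A vanishing denominator (zero mean,
zero spread, zero IQR) raises an error instead of returning zeros: real
detector data never has exactly zero spread, so hitting one indicates a
pipeline bug upstream.

## Feature pooling

Five pooling operators per normalized block (R channels, T frames):

| token | definition | length |
|---|---|---|
| `rf` | channel-major flattening | R·T |
| `tsd` | per-channel std over time | R |
| `ssd` | per-frame std over channels | T |
| `tf` | TSD ++ SSD | R+T |
| `sf` | six scalar heterogeneity biomarkers | 6 |

The six SF biomarkers compose two reductions (mean or population std) over
the two axes.  Of the eight ordered compositions, the two all-mean ones
coincide with the global mean — uninformative after normalization — and are
dropped.  Canonical order:
`[μ_s(σ_t), σ_s(σ_t), σ_s(μ_t), μ_t(σ_s), σ_t(σ_s), σ_t(μ_s)]`,
where `*_t` reduces time (length-R result) and `*_s` reduces channels
(length-T result).  This enumeration reproduces the biomarker count of the
hypothesis-driven analyses this pipeline is compared against and contains
both of their named examples; their exact original ordering is not
recoverable, so this package's order is fixed and documented here.  SF of a
constant block is the zero vector (all six metrics are well defined there),
whereas pooling a block with a singleton axis raises.

## Representations

A representation spec is (wavelength set, normalization subset, pooling):
wavelengths one of {760}, {830}, {760, 830}; normalization subsets of size
1–3 of the 4 methods (never empty, never all four); one pooling.  That is
3 x 14 x 5 = 210 unilateral representations.  The subset-size bounds are
exposed as parameters of the enumerator so other readings of the design
space can be explored; the defaults are the unique natural reading that
yields 210.  Enumeration order is deterministic and lexicographic
(wavelength choice, subset size/position, pooling).

Concatenation (early fusion) order is wavelength-major, then normalization
in the fixed method order (relative_change, zscore, zero_center, robust).
The classifier is order-invariant given consistency; fixing the order makes
results bit-reproducible.

The bilateral representation replaces each single-feature part by the plain
Euclidean distance between its right- and left-breast versions (no
dimension normalization), giving one non-negative scalar per part.
Distances are accumulated part by part without materializing the
concatenated unilateral vectors, so raw-feature bilateral specs run in
memory proportional to one block.

## Split protocol, classifier, selection

Classification units are breasts in unilateral mode (the tumour-bearing
breast is the positive unit; the contralateral breast of a patient is a
negative unit) and subjects in bilateral mode.  Held-out sizes use
`floor(frac * n)`; with 63 subjects and 20 % fractions this yields 126
breast units split 101/25, shuffle splits of 81/20 within the 101, and
41/10/12 subjects bilaterally.  In unilateral mode the two breasts of one
patient may land in different subsets by design (an optional grouped mode is
out of scope here).  The test set and each validation set are drawn
stratified by label with largest-remainder per-class allocation, keeping
label ratios within one unit of proportionality — with 12–25 test units an
unstratified draw can produce single-class test sets, which break AUC.  The
20 shuffle splits are drawn once and shared across all (spec, C) candidates,
so candidate comparisons are not confounded by split noise.

The classifier is a maximum-margin linear SVM (hinge loss, inverse
regularization C), provided by scikit-learn's libsvm binding with a linear
kernel; training is deterministic given the samples and C.  Features enter
exactly as built — the normalizations under study are the only rescaling.
The default C grid is 7 values log-spaced over 10⁻³…10³ (configurable; the
search space is not dictated by the method).  The winning (spec, C) pair
maximizes mean validation AUC; ties break toward the smaller feature
dimension, then candidate order, then smaller C.  The winner is retrained on
the full model-selection set and scored on the test set exactly once.

ROC curves sweep thresholds over distinct score values; the AUC is computed
as the trapezoidal area, which equals the Mann–Whitney pair statistic
(ties one half) — the test suite verifies that identity against exhaustive
pair counting and against scikit-learn.  Thresholded sensitivity/specificity
pairs are deliberately not reported: with a dozen test units the ROC curve
is strongly discretized and any single operating point would be misleading.

The sparse-grid ablation re-runs selection and evaluation (hyperparameter
re-selection included, same plan seed) on channel subsets.  Grid geometries
are user-supplied configurations; the package ships an evenly-spaced-comb
constructor as a reasonable default for homogeneous spatial coverage, since
actually deployed sparse layouts are instrument-specific curation.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes.  Per
channel `r`, side `b`, wavelength `w`:

```
x(r, t) = g_r * (1 + c_r * s_bw(t) + l_r(t) + u_r(t) + eps(r, t))
```

* `g_r` — channel gains, log-uniform over `gain_log10_range` decades
  (default 4): continuous-wave transillumination spans an enormous dynamic
  range set by per-channel coupling and attenuation.  Gains are drawn per
  subject and shared between sides and wavelengths, modelling one fibre
  interface with roughly mirror-symmetric optode placement.
* `s_bw(t)` — systemic vasomotion: `n_vasomotion_components` (default 3)
  sinusoids with frequencies uniform in `vasomotion_band_hz` (default
  0.01–0.1 Hz), amplitudes scaled so the summed rhythm has RMS equal to the
  subject's amplitude.  Component frequencies, amplitudes and base phases
  are subject-level physiology; each side sees them with a small
  side-specific phase lag (`side_phase_jitter_rad`, default 0.1 rad),
  reflecting that sub-0.1 Hz rhythms are largely systemic and near-coherent
  across body sides.  The two wavelengths see the rhythm with correlation
  `wavelength_correlation` (default 0.8).  The per-channel modulation depth
  `c_r` varies around 1 (per-subject spread up to `channel_depth_max`,
  default 0.6).
* `l_r(t)` — local vasomotion: one sinusoid per channel, incoherent across
  channels, present in every subject with a per-subject level
  (`local_fraction_range`, default 0.25–1.0 relative to the systemic RMS);
  per-channel frequency and phase are mirror-symmetric between sides up to
  the same phase lag.
* `u_r(t)` — the tumour effect: in the tumour-bearing breast only, a
  contiguous source-major band of `ceil(tumor_channel_fraction * R)`
  channels (default fraction 0.15) receives an extra incoherent
  low-frequency component scaled so each affected channel's fluctuation
  variance is multiplied by `1 + effect_size`; `effect_size = 0` is the
  exact null.
* `eps` — white noise, uniform with half-width `noise_rel_amplitude`
  (default 0.02).  Uniform rather than Gaussian noise keeps intensities
  strictly positive by construction, so relative-change normalization never
  divides by ~0 on synthetic data.

Between-subject variability — overall rhythm amplitude (log-normal,
`subject_amplitude_sd_log` = 0.4), modulation-depth spread, local-vasomotion
level — is shared by the two breasts of a subject.  This structure is the
load-bearing design choice of the generator: it is what lets bilateral
referencing cancel physiological confounds while leaving unilateral
classification genuinely hard, the qualitative ordering the pipeline is
meant to detect.  Without it (all subjects statistically identical), a
linear classifier separates tumour breasts from controls almost perfectly
and the bilateral advantage disappears; with inter-subject variability but
no universal local-vasomotion component, the tumour signature (spatial
incoherence) would be qualitatively unique to patients and again linearly
separable unilaterally.  Both failure modes were observed during design and
are the reason the local component exists in every subject.

Defaults mirror the clinical study conditions: 63 subjects, prevalence
18/63, 32 x 64 channels, 400 frames at 1.8 Hz.  Cancer-positive subjects
(`round(prevalence * n)`, half-up) are drawn at random from a cohort-level
stream; tumour laterality is uniform per positive subject.  Each subject's
signal content comes from a substream keyed by (seed, subject index), so
cohorts of different sizes share the signal of their leading subjects;
generation is a pure function of the seed.

What the generator does **not** model: photon transport or diffusion,
hemoglobin spectra (the two wavelengths differ only by the correlation
parameter, not by physiologically distinct contrast), spatially realistic
tumour sensitivity profiles (the affected band is contiguous in channel
index, not in anatomical space), motion artifacts, provocation maneuvers,
or heart-rate/respiratory bands.  Passing recovery tests therefore show
that the pipeline detects localized one-sided variance elevation against
realistic gain, rhythm and between-subject structure — they do not certify
performance on clinical data.

## Validation experiments

The acceptance suite (and `scripts/acceptance.py`) runs the pipeline at a
reduced 8 x 16 x 100 scale with 63 subjects — small enough for the full
protocol (20 shuffle splits, 7-point C grid, six SF candidate
representations) to run in seconds per cohort while the 100-frame records
still resolve the vasomotion band:

* **Recovery**: at `effect_size = 2.0`, the bilateral SF pipeline averages
  test AUC ≈ 0.92 over five seeds and exceeds the matched unilateral
  pipeline (≈ 0.69), reproducing the bilateral ≫ unilateral ordering that
  motivates bilateral instrumentation.
* **Null calibration**: at `effect_size = 0`, twenty seeds give a mean test
  AUC ≈ 0.5 (single-cohort values scatter widely, as expected with 12 test
  subjects), confirming the selection procedure does not manufacture signal
  despite searching over representations and hyperparameters.
* **Structural and operator checks**: feature lengths at full scale
  (819 200 / 2 448 / 2 048 / 400 / 6), the 210-spec enumeration, the split
  arithmetic above, brute-force loop oracles for every normalization and
  pooling (1 000 random blocks, 1e-10 relative), and the trapezoid =
  pair-counting AUC identity (1 000 cases, 1e-12).

## Numerical choices and degenerate inputs

* Population std everywhere (normalizations, poolings, SF metrics).
* Selection tie-break: feature dimension, then candidate order, then C.
* Single-class training sets, all-identical feature matrices, and
  single-class AUC evaluations raise typed errors with context (spec, C,
  split index) rather than returning defaults.
* The spectral check (band-power fraction) uses a rectangular-window DFT;
  on short records leakage across the 0.01 Hz band edge is expected, and
  band-limitedness assertions use records long enough to resolve the edge.
* Seeds: every stochastic stage takes an explicit seed; split plans and
  cohorts derive their streams from `SeedSequence` hierarchies, so results
  are bit-reproducible across platforms running the same library versions.

## Known limitations

* The SF biomarker ordering is a package convention (see above).
* The bilateral distance is the plain Euclidean norm; parts of very
  different dimensionality (e.g. RF vs SF within one spec) contribute on
  different scales, which is faithful to the method under study but means
  bilateral multi-pooling fusions are scale-dominated by the longest part.
* Unilateral mode intentionally allows the two breasts of one patient to
  fall into different subsets, mirroring the studied protocol; this leaks
  subject-level information and slightly flatters unilateral scores.
* AUC confidence intervals are not provided; test sets of 12–25 units make
  single AUC values noisy, and summary experiments should average over
  seeds (as the acceptance experiments do).
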