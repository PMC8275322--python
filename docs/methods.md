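# Methods

This note records the model behind `rawms`, the conventions the
implementation pins down, what the synthetic-data generator does and does
not emulate, and the design choices made where more than one reasonable
option existed.

## The pipeline model

A SWATH/DIA acquisition of one sample consists of an MS1 scan series
(precursor spectra, m/z 400–1249) and K MS2 scan series, one per precursor
isolation window, each fragment spectrum covering m/z 0–2000. `rawms`
treats each scan series as a sparse set of (RT, m/z, intensity) points and
converts it to a fixed-size image, so that a pretrained image encoder can
produce generic "off-the-shelf" features for a conventional classifier.
Peptide identification, spectral libraries and protein quantification are
deliberately absent; externally produced quantification matrices can still
enter the comparison through `features.load_tabular_features`.

## Rasterization conventions

- **Axes.** Rows are RT bins ascending downward, columns are m/z bins
  ascending rightward. The m/z axis is fixed to [0, 2000] Th for MS1 and
  MS2 alike, so MS1 content (400–1249 Th) sits in the interior and the
  flanking columns are implicit black padding — absent points simply leave
  zero cells, which is equivalent to concatenating black pixel blocks.
- **Bins.** Half-open [lo, hi) with the top edge closed:
  `col = floor(mz/2000·G)` clamped to G−1, and likewise for RT. Coverage
  is total and non-overlapping; G ≥ 2 is accepted, 512 and 2048 are the
  study-scale sizes.
- **Aggregation.** A cell's value is the arithmetic mean over the recorded
  points assigned to it; cells with no points are 0. Averaging over
  recorded points only (rather than including implicit zeros) keeps the
  padding exactly black and makes the operation independent of how points
  are distributed over scans with equal RT. The implementation accumulates
  points in recorded order, so it agrees *exactly* (not just to rounding)
  with a per-point reference loop.
- **RT normalization** is per scan series. The default `per_run_minmax`
  maps each series' own [rt_min, rt_max] onto the grid, emulating the
  scaling of runs with similar durations onto a uniform time axis;
  `fixed_duration` maps [0, T] for callers who prefer an absolute clock.
  A series without RT extent is an error rather than a guess. Empty RT
  bins between scans are left at zero (no interpolation), and no retention
  time alignment across runs is attempted.
- **Intensities** stay raw-scale floats internally. Dynamic-range
  compression (`log1p_then_linear`) is offered at export/encoding time,
  default `linear_max` (none).

## Image preparation and encoders

`prepare_image` applies, in order: the intensity transform; scaling to
[0, 1] by the per-image maximum (all-zero images stay zero; per-image
rather than per-dataset because each image is encoded independently);
bilinear resize from G×G to the encoder's S×S; triplication of the gray
channel to three identical RGB channels; optionally an affine map to
[−1, 1] for encoder families that expect symmetric inputs. Bilinear
resampling is pinned to the half-pixel-center (align-corners-false)
convention so results are bit-stable and testable against the direct
formula.

Encoders are callables with an `EncoderSpec` (name, input side S, output
dimension D, pixel scaling). The built-in **reference encoder** mean-pools
the first channel into P×P blocks (P=32 by default, so 7×7-pixel blocks at
S=224) and applies a fixed random linear projection (Gaussian entries,
1/√(P²) scaling) to D dimensions drawn once from its seed. It is linear in
the pooled image, deterministic forever for a given seed, and requires no
network or weights — it stands in for pretrained networks so the pipeline
is fully testable offline; it does not attempt to reproduce any specific
network's numerical outputs. External pretrained models plug in through
`load_external_encoder`, either as an importable factory
(`python:module:attr`) or a TensorFlow Hub handle behind an optional
backend; each adapter must document its own pixel-scaling expectation,
and declared output dimensions are verified on a probe image.

## Feature assembly and constant features

Per-sample vectors are concatenations in a canonical order — MS1 first,
then MS2 windows ascending by window lower bound — either `ms1_only`
(length D) or `ms1_and_ms2` (length D·(1+K)). A missing window vector is
an error, never zero-filled, since silent zero-fill would fabricate black
spectra. Constant features — columns whose entries are all exactly equal
(encoder outputs are deterministic floats, so no epsilon is used) — are
removed, by default over **all samples**; a leakage-free `train_only`
scope exists because dataset-level removal technically sees test rows,
even though dropping globally-constant columns cannot carry label
information. The retained-feature mask and retention fraction are kept on
the matrix.

## Classification protocol

- **Split:** stratified, per-class test counts `round(n_c · fraction)`
  (default fraction 0.30), seeded within-class shuffles.
- **Scaling:** per-feature min–max to [0, 1], fit on training rows only.
  A constant training column maps every value, including test values, to
  0; test values are otherwise not clipped.
- **Hyperparameters:** shallow grids — logistic regression C ∈
  {0.1, 1, 10, 100}; SVC C ∈ {0.1, 1, 10, 100} × kernel ∈ {linear, poly,
  rbf}; random forest and gradient-boosted trees n_estimators ∈
  {100, 500}; all other settings are the libraries' defaults
  (scikit-learn; XGBoost for the boosted trees). Selection is by the mean
  of the 12 fold AUCs from 2 repeats of stratified 6-fold CV, each repeat
  reshuffled with its own derived seed; ties go to the first-listed grid
  point.
- **Scores vs probabilities:** ranking metrics (AUC) use the continuous
  decision value where one exists (margins for logistic regression and
  SVC) and the class-1 probability for tree ensembles; Brier and log loss
  need probabilities, so SVC uses Platt-style internal calibration.
  Log loss floors probabilities at 1e-15. Thresholded metrics classify at
  probability 0.5; Youden's J is maximized over ROC thresholds, hence
  never below sensitivity+specificity−1 at the fixed threshold.
- **AUC** is computed as the Mann–Whitney statistic with ties counting
  one half, which equals trapezoidal ROC integration.
- **Seeds:** every stage derives its seed as `crc32(master:label)` —
  split, each CV repeat, each fold fit, the refit — so one master integer
  reproduces an evaluation exactly, and changing one stage's label space
  never perturbs another stage.

Splits are sample-level. Cohorts with technical replicates of one biopsy
should group replicates before splitting to avoid replicate leakage; the
split operates on whatever rows the caller provides, so grouping amounts
to passing one row per subject or filtering afterwards.

## Benchmarking statistics

Sweeps evaluate every (resolution × encoder × input mode × classifier)
configuration with per-configuration derived seeds; failures are recorded
per row and do not abort the sweep. Per-encoder summaries report median,
mean and sample (n−1) standard deviation of AUC pooled over classifiers
and resolutions (single-row groups report σ=0 with n=1 flagged). Matched
configuration pairs differing only in input mode (or only in resolution)
feed a classical one-sided paired t-test (degenerate zero-variance
differences raise rather than returning NaN) and Spearman rank
correlations (average ranks on ties; constant sequences raise).

## The synthetic-data generator

The generator emulates the *structure* of a SWATH acquisition, not its
physics. Per run: `n_scans` evenly spaced RTs over an `rt_span` of 600 s;
each peptide-like peak contributes a precursor point (at its fixed
precursor m/z) to MS1 and one point per fragment to exactly the MS2
series whose isolation window contains the precursor (windows are K
contiguous tiles of 400–1249 Th, so routing is unambiguous; real
overlapping schemes can be read from files but are never generated).
Intensities follow a Gaussian elution profile times a multiplicative
lognormal noise draw (σ=0.3); every scan additionally receives 20
background points uniform in m/z with exponential intensities (scale 10).
Class 1 multiplies discriminative peaks by a fold change — in both MS
levels, or only in the fragments (`ms2_only`), which makes MS1
distributionally identical between classes and isolates the value of
including MS2 features.

Default study conditions: 30 samples per class, K=10 windows (desk-scale
stand-in for the 100-window acquisition geometry; K=100 is one config
field away), 20 peaks of which 5 discriminate at fold change 4, reference
encoder D=256 at grid size 512. At these settings the end-to-end held-out
AUC is essentially 1 with the signal present, near 0.5 with fold change 1,
and `ms1_and_ms2` beats `ms1_only` when the signal is fragment-only.

What the generator does **not** model: isotope envelopes, charge states,
chromatographic tailing, retention-time drift between runs, batch
effects, correlated noise, or realistic peptide densities (real MS1 scans
carry orders of magnitude more points). Passing tests therefore
demonstrate that the pipeline's plumbing, determinism and statistical
protocol are correct and that it recovers planted signal of a known
effect size — not that any particular classification performance will be
attained on real cohorts.

## File formats

mzML 1.1 and mzXML are read (mzXML via pyteomics; mzML via a small
namespace-aware XML reader handling the standard controlled-vocabulary
parameters: ms level, scan start time with minute/second units, isolation
window target/offsets, 32/64-bit float arrays, zlib or uncompressed).
Written files use a minimal mzML 1.1 / mzXML dialect (centroided spectra,
64-bit float arrays) that round-trips through the readers to 1e-6
relative tolerance; RTs are normalized to seconds on read. Isolation
windows are grouped with a 0.01 Th tolerance to absorb storage-precision
differences across files, and window membership always comes from the
file's precursor metadata, never recomputed from fragment m/z. Grid
export offers lossless float arrays (`array64`; `array32`/`array16` for
smaller files) and 8/16-bit PNG with per-image max scaling.

## Known limitations

- The reference encoder is a fixed linear sketch; it validates the
  pipeline but is far weaker than a deep pretrained encoder on real data.
- Dataset-level constant-feature removal is the default for fidelity to
  the benchmarking protocol, despite its (benign) test-row visibility.
- No retention-time alignment, noise filtering or batch correction.
- SVC probabilities come from Platt calibration inside the SVC fit, which
  is known to be imperfect on small training sets; AUC is unaffected
  since it uses margins.
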