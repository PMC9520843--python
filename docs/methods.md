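# Methods

This note documents the models, parameter choices and numerical decisions
behind `endovesiq`, in the spirit of a methods section a maintainer can
audit.

## Synthetic image model

The simulator emulates single-plane confocal fields of punctate endocytic
vesicles. It is the ground-truth harness for the analysis pipeline, so its
defaults define the study conditions under which the pipeline is validated.

**Vesicles.** The vesicle count per field is Poisson with mean
`vesicle_density × rows × cols / 1000` (density in vesicles per 1000 px²).
Centres are placed by dart throwing with a minimum centre separation of
`min_separation × (r_i + r_j)` (default 1.0), keeping one radius of margin
from the field edge; at the default densities the rejection loss is
negligible, so the realised counts remain Poisson to within sampling error.
Radii are uniform on `radius_range` (default 2–5 px). Each vesicle is
rendered as an isotropic 2D Gaussian with σ = radius/2 — diffraction-blurred
puncta, deliberately not hard disks, so thresholding is non-trivial — with
per-vesicle peak amplitudes lognormal around `primary_amplitude` with
CV `amplitude_cv` (default 0.2).

**Secondary markers.** Each secondary channel has its own Bernoulli
`true_positive_fraction` per vesicle, independent across vesicles and
channels. A truly positive vesicle's peak in that channel is its base
amplitude times `enrichment_factor` (default 1.5); a negative vesicle
receives `bleed_fraction` (default 0.1) of that enriched amplitude as
spectral bleed-through, so negatives are dim but not black and the
classifier has a real decision boundary.

**Background and noise.** The background is a low-frequency Gaussian random
field: white noise smoothed at `background_smoothness` (default 40 px),
normalised to mean `background_level` exactly, with relative sd
`background_variation`. Noise is the standard camera model: Poisson on the
expected signal, then additive Gaussian read noise (`gaussian_noise_sd`,
default 5), clipped at zero.

**Photometric calibration of the defaults.** With background B = 400,
primary amplitude A = 220, enrichment factor 1.5 and bleed 0.1, the mean
intensity over a detected mask is roughly 0.5–0.7 of the peak amplitude, so
truly positive vesicles sit ≈ 40–50% above the image mean and negatives
≈ 4–5% above — comfortably separated by the 15% rule on both sides. The
background variation default is 0.05: at 0.10 the smooth background alone
shifts per-vesicle enrichment ratios by up to ±0.1, which pushes negative
vesicles over the 1.15 cutoff and biases recovered positive fractions
upward. Amplitudes are arbitrary units on a 16-bit-like scale; only ratios
matter to the classifier.

**Condition presets.** The LSS preset (default 256×256 fields, density 0.8,
positive fractions 0.6/0.5/0.45 for endoglin/eea1/smad1) versus the HSS
preset (density 0.4, fractions 0.35/0.3/0.25) encodes the qualitative
experimental contrast the pipeline must resolve: more vesicles and higher
marker positivity under low shear. Real per-field magnitudes are not
published as numbers, so these are order-of-magnitude choices, not
measurements. Sub-seeds per field derive deterministically from
(master seed, condition label, field index) via `numpy` seed sequences.

**What the simulator does not model.** No 3D/z-stacks, no realistic PSF
beyond Gaussian blur, no cell boundaries or nuclei, no spatial clustering
of vesicles, no channel misregistration, no marker-intensity correlation
beyond the Bernoulli labels. Passing tests therefore demonstrate that the
pipeline recovers known truth under this generative model, not that it is
robust to every artefact of real micrographs.

## Detection

`detect_vesicles` runs: Gaussian pre-smoothing (`smooth_sigma`, default
1 px) → white top-hat with a disk of `background_radius` (default 15 px) →
automatic threshold → optional hole filling → connected components
(8-connectivity default) → area and circularity filters → consecutive
relabeling.

Numerical choices worth knowing:

- The disk structuring element uses scikit-image's sequence decomposition
  for speed; it is a close approximation of the exact disk, and the
  subtracted raster is clipped at 0 to keep the top-hat's non-negativity
  contract.
- Pre-smoothing exists because a white top-hat of shot-noisy data leaves a
  broad positive noise residual in which histogram-based thresholds sit too
  low; 1 px of smoothing suppresses single-pixel noise while barely
  attenuating blobs with σ ≥ 1.
- Automatic thresholds (Otsu default; triangle and mean+k·sd available) are
  floored at `median + noise_floor_k × 1.4826 × MAD` (default k = 5) of the
  subtracted raster. Signal pixels are sparse, so median/MAD estimate the
  noise scale; the floor makes a signal-free image yield zero detections
  instead of a split noise histogram. A fixed numeric threshold bypasses
  the floor.
- Circularity is the ImageJ convention 4πA/P² with the perimeter from
  scikit-image's weighted contour estimator, capped at 1 (small components
  can otherwise exceed 1); components with zero perimeter count as
  circular. Area and circularity bounds are inclusive.
- Centroids are intensity-weighted on the background-subtracted raster;
  coordinates are 0-based (row, col).
- Touching blobs are not split by default (no evidence the original
  workflow did); a distance-transform watershed is available behind
  `split_touching`.
- Default particle filters (min area 4 px², max 400 px², min circularity
  0.3) are typical endosome scales at confocal sampling — documented
  choices, all overridable.

On the simulator's defaults this detector reaches precision ≈ 1.0, recall
≈ 0.96–0.98 and centroid RMSE ≈ 0.35 px at peak SNR 5 (amplitude = 5× the
background noise sd), as recomputed by `scripts/acceptance.py`.

## Enrichment classification and screening

The rule: vesicle mean intensity in a marker channel ≥ (1 + f) × reference,
f = 0.15. Interpretation decisions, each configurable:

- **Reference scope** — "mean intensity of the image" is read literally as
  the mean over *all* pixels of that channel's raster (`image_mean`);
  `outside_mean` (non-vesicle pixels) and `image_median` are selectable.
- **Raster version** — intensities are measured on the raw channel, not the
  background-subtracted one (subtraction serves detection); `measure_on`
  switches this.
- **Boundary** — "at least 15% higher" is inclusive (≥); a strict mode
  exists but is not default.
- **Statistic** — the vesicle *mean* (not integrated intensity) is
  compared; the table retains areas so integrated intensity is recoverable.
- **Per-image baseline** — the reference is computed per image, matching
  the per-image wording of the rule.
- **Screening** — no separate numeric criterion is defined for "signal" of
  additional markers, so screening applies the same enrichment rule
  (per-marker `f` overridable). Vesicles failing the base marker set get
  co-positivity `False`, never missing, making the flag an exact
  conjunction.

The rule is scale-invariant (multiplying a channel by c > 0 changes
nothing), monotone in f, and reduces to `mean ≥ image mean` at f = 0.

Line profiles use bilinear interpolation at `n_samples` equispaced points,
averaged over `width` parallel 1-px-spaced offsets perpendicular to the
segment — matching common viewer behaviour and deterministic.

## Quantification and statistics

Counts are per field of view; per-cell normalisation is out of scope (no
cell segmentation). The default two-condition test is Welch's unequal-
variance t-test (robustness over the classical pooled test, which remains
available as `student`, as does a permutation test on the difference of
means). Two degenerate cases are defined explicitly: identical zero-variance
groups give t = 0, p = 1; zero-variance groups with different means give
p = 0. Multiple markers are not multiplicity-corrected by default (tests
are per panel); apply your own correction if you screen many markers.

Ground-truth matching is greedy nearest-neighbour in ascending distance
order (ties broken by label then id, so it is invariant to detection
ordering), each side used at most once, gated at `max_dist`. Precision is
undefined (reported as absent) with zero detections, recall with zero
truths. For non-overlapping vesicles greedy matching equals optimal
assignment.

Calibration under the null (identical presets for both conditions) was
checked by simulation: the Welch test on per-field detected counts rejects
at α = 0.05 in ≈ 3% of 100 replicate experiments — inside the binomial
95% band around the nominal rate; with LSS density double HSS and 10
fields per condition the rejection rate is ≈ 1.

## Problem sizes used in the test suite

The validation suite uses 512×512 fields (≈ 200 vesicles) for detection and
classification-recovery benchmarks (20 seeds per setting), 160×160 fields
with 5–10 fields per condition for the 100-replicate null calibration and
the 25-replicate power check, and 96–256 px fields elsewhere. These sizes
give sampling errors comfortably below the tolerances being asserted while
keeping the full suite fast.

## Pipeline and reproducibility

One master seed drives everything: field sub-seeds, noise, and the
permutation test. `endovesiq run` writes the config snapshot next to its
outputs; replaying that snapshot with the same seed reproduces every CSV
byte-identically (outputs go directly into the chosen directory so reruns
are diffable). Unreadable input images are recorded per file and the run
continues, with a partial-failure exit code (3) from the CLI.

## Known limitations

- The enrichment reference uses the whole image including the vesicles
  themselves; on fields where vesicles occupy a large area fraction this
  raises the baseline and makes the rule conservative.
- Otsu with the MAD floor assumes sparse signal; images dominated by
  foreground should use a fixed threshold.
- Greedy matching can differ from optimal assignment in dense fields with
  overlapping vesicles.
- The t-test treats fields as independent replicates; vesicles within a
  field are not modelled hierarchically.
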