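# Methods

This note records the models implemented in `dticonn`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Signal model and tensor estimation

The forward model is the single-compartment Stejskal-Tanner attenuation
`S = S0 · exp(−b gᵀ D g)` with a symmetric positive semi-definite tensor
`D` in mm²/s. The estimator is ordinary log-linear least squares: with
`y = −ln(S/S0)` and design rows `b·[gx², gy², gz², 2gxgy, 2gxgz, 2gygz]`,
the six unique components solve `y = X d` per voxel. `S0` is the mean of
the b = 0 measurements; signals are floored at `1e-6 · S0` before the log
so noise can never produce a non-finite fit. The estimator is deterministic
and closed-form; weighted or nonlinear least squares would be preferable at
very low SNR but the log-linear fit is accurate at the SNRs used here
(noiseless recovery is exact to machine precision; at snr = 20 the median
principal-direction error over a ~1100-voxel bundle is ≈ 1.5°). The fit is
swappable behind `fit_tensor_loglinear`.

Eigenvalues are sorted descending. Negative eigenvalues (possible under
noise) are clamped to zero and the voxel flagged `low_confidence` rather
than rejected; the same flag marks a degenerate λ1 ≈ λ2 tie
(|λ1 − λ2| < 1e-12), for which the decomposition's first vector is returned
deterministically. Tracking treats low-confidence voxels like any valid
voxel. The principal eigenvector is stored under a fixed sign convention
(first component of magnitude above 1e-12 is positive); sign is
re-disambiguated during tracking.

Fractional anisotropy is the usual normalized eigenvalue dispersion,
clipped to [0, 1]; it is a utility output and does not enter the
statistics.

## FACT tracking

Tracking is the voxel-boundary-intercept form of FACT rather than
fixed-step Euler: from the seed-voxel center, the track advances along the
current direction to the exact exit point of the current voxel (ray-box
intersection), crosses into the next voxel nudged by `step_epsilon`
(default 1e-4 voxels, which also resolves edge/corner hits), adopts that
voxel's principal eigenvector with its sign flipped if needed to keep a
non-negative dot product with the incoming direction, and repeats.
Termination: leaving the grid or mask, entering a voxel without a valid
tensor, a direction change above `angle_threshold_deg` (default 60°,
boundary inclusive — exactly 60° continues), or the `max_steps` cap
(default 10,000 per half-track). Two half-tracks are launched along ±e1
and concatenated; bidirectional launch is required for a fiber to reach
two different regions and is standard FACT practice.

Coordinates are voxel-space throughout (voxel (i,j,k) spans
[i, i+1)×[j, j+1)×[k, k+1)); the affine enters only at TRK export. The
eigenvector is used directly as the index-space step direction, which is
exact for isotropic voxels and a good approximation for the near-isotropic
voxel sizes used here (default 2 mm isotropic; clinical DTI voxels are
typically within a few percent of isotropic in-plane).

"Tissue and its neighbors" is realized as a 1-voxel 26-connected dilation
of the tracking mask. Dilated voxels are entered (and seeded) only where
the tensor field is valid, i.e. where the fit mask covered them; on
phantoms the fit mask equals the bundle mask, so the dilation is inert and
fiber counts are exact.

## Connectome

Endpoint regions are the labels of the voxels containing the two terminal
points — no neighborhood search, which is the simplest reading of
"endpoints inside the regions". Streamlines with a background endpoint or
both endpoints in one region are discarded (the network is used edge-wise
between distinct regions, so self-loops carry no information). Entries
below `min_fibers = 5` streamlines are zeroed per subject; an entry of
exactly 5 is retained. The packaged region table has 39 motor-related
regions (19 bilateral pairs plus brainstem) grouped into motor/premotor,
DLPFC, cingulate motor area, SMA, parietal, subcortical and brainstem
clusters; matrix row order follows the table so per-subject CSVs are
directly comparable.

## Group statistics

The per-edge statistic is the raw difference of group means of fiber
counts (group A − group B). Each of the 10,000 default permutations
randomly reassigns the fixed group sizes to subjects and recomputes all
edge statistics; testing is two-sided via |T| because effects in both
directions are of interest. Monte-Carlo p-values use the add-one estimator
`(1 + #{perm ≥ obs}) / (n_perm + 1)`, which is valid and never zero; the
exhaustive mode enumerates all C(n, n_a) assignments and reports exact
proportions. Family-wise correction is the single-step max-|T| method:
the corrected p of an edge compares its observed |T| with the permutation
distribution of the maximum |T| over all tested edges. This construction
is self-contained (it needs only the same permutation null), and the
uncorrected p is reported alongside so per-edge percentile-of-null
readings are also available. Edges that are zero in every subject are
untestable and excluded from the family.

Spearman's coefficient is computed as average ranks followed by Pearson
correlation of the ranks; the raw p uses the large-sample t approximation
`t = ρ√((n−2)/(1−ρ²))`, adequate at the cohort sizes used (n = 77).
Constant edges are excluded as undefined. Holm-Bonferroni step-down
correction is applied over the tested family, with adjusted p
`min(1, cummax((m−k+1)·p_(k)))`.

## Classifier

A linear SVM (hinge loss, C defaulting to 1.0 — the regularization is not
critical for the well-separated feature sets produced by the screens and is
exposed as a flag) evaluated by leave-one-out cross-validation. Features
are standardized with each training fold's mean/SD so the scaling never
sees the held-out subject. Feature selection (the screened edges) is
performed once on the full cohort by default, matching a screen-then-
classify protocol; because that protocol is optimistically biased, the
pipeline also offers `feature_selection: per_fold`, which repeats both
screens inside every training fold and is flagged in the output.

The positive class for sensitivity defaults to the first group (the
SWEDD-like group in the generated cohorts) and is recorded in every
report. A caution on null behavior: leave-one-out accuracy on data with no
class signal is high-variance and biased *below* chance (removing a
subject tips the training fold's class balance against that subject's own
class), so single permuted-label runs can land far outside the nominal
chance band; chance-level checks in this package therefore average over
permutation seeds.

## Synthetic phantoms

`make_bundle_phantom` rasterizes bundles along polyline paths: every voxel
whose center lies within `width/2` (voxel units) of the path gets an
axially symmetric tensor `D = λ_r I + (λ_a − λ_r) t tᵀ` oriented along the
analytic tangent of the nearest segment (defaults λ_a = 1.7e-3,
λ_r = 0.2e-3 mm²/s, FA ≈ 0.87 — a strongly coherent white-matter bundle);
background voxels are isotropic at 0.7e-3 mm²/s. Paths are polylines
rather than smooth arcs: a sharp two-segment elbow produces a controlled
single-voxel direction change, which is what the angle-threshold rule acts
on (a gently curved arc changes direction by only a few degrees per voxel
and is followed correctly). Region labels occupy the bundle-end voxel
slabs (`label_thickness` of arclength, default one voxel), so every
correctly tracked streamline terminates inside a labeled region.
Overlapping bundles with non-parallel orientations raise an error — a
single-tensor voxel cannot represent a crossing, and silently averaging
would fabricate geometry.

Noise is Rician, applied per measurement as the magnitude of the complex
signal plus independent Gaussian components of scale σ = S0/snr. The
default is noiseless (snr = ∞): the phantom's role is exact geometric
validation, and noise levels are chosen explicitly where a test needs them
(snr = 20 for direction-error calibration, a typical clinical DWI regime).
At low SNR the Rician floor biases the mean signal upward, which the
generator reproduces.

What the phantoms do **not** emulate: head anatomy, partial-volume and
multi-compartment signals, crossing fibers within a voxel, and
motion/eddy artifacts (real pipelines correct these upstream). Passing
phantom tests therefore validates the tracking and counting machinery, not
robustness to in-vivo confounds.

## Synthetic cohorts

`make_cohort` draws per-subject symmetric integer matrices with
negative-binomial edges — fiber counts in real connectomes are
overdispersed, with SD of the same order as the mean. Defaults emulate the
study conditions the package targets: 37 vs 40 subjects, 39 regions,
baseline mean 20 and dispersion θ = 3 (coefficient of variation ≈ 0.6,
the range shown by published fiber-count tables), four planted edges —
placed at the four connections reported to separate the groups — with
multiplicative shift 2.5 in the PD-like group (published group ratios at
the strongest edges are ≈ 2.1–2.5), and a clinical score
`round(Σ 0.15·w_e + N(0, 4))` floored at 0, giving an integer
MDS-UPDRS-III-like score (mean ≈ 20) whose pooled Spearman correlation
with each planted edge is ≈ 0.6. All four planted effects are increases:
under the raw mean-difference statistic with a shared baseline mean, a
decreased edge has a much smaller absolute effect and cannot compete with
the max-statistic threshold set by the increased edges, so mixed-direction
planting is exercised in dedicated unit tests (smaller families, where a
shift of 0.4 with a negative score slope yields the expected negative
correlation) rather than in the joint-recovery demo.

The score model is a stand-in, not a claim about any real cohort: real
MDS-UPDRS distributions, their relation to connectivity, and between-edge
correlation structure are not modeled. All randomness flows from one seed
through `numpy.random.SeedSequence` spawning; identical specs are
bit-identical.

## Problem sizes used in the validation suites

Chosen as the package's own validation scales: phantom recovery uses a
50-voxel straight bundle and a ~290-voxel elbow; direction-error
calibration a ~1100-voxel bundle at snr = 20; Monte-Carlo-vs-exhaustive
agreement 100 runs of 4 vs 4 subjects with 10,000 draws against the exact
C(8,4) = 70 enumeration; family-wise calibration 200 null cohorts
(39 regions, 37 vs 40) at 2,000 permutations (p resolution 5·10⁻⁴, far
below the 0.05 level being calibrated); planted-edge recovery 50 seeded
cohorts at the full 10,000 permutations.

## Known limitations

- Single-tensor model: no crossing-fiber or multi-shell support (HARDI-
  style models are out of scope).
- Tracking uses nearest-voxel directions without trilinear interpolation
  and no FA-based stopping; this matches the boundary-intercept FACT
  definition but differs from many modern deterministic trackers.
- The statistic is the raw mean difference, so edges with larger baseline
  counts dominate the max-statistic family; a studentized variant would
  equalize scales but is not what the implemented protocol specifies.
- The screen-then-classify default is optimistically biased; use
  `feature_selection: per_fold` for honest generalization estimates.
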