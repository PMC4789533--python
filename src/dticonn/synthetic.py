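"""Synthetic diffusion phantoms and synthetic connectivity cohorts.

Two generators make every downstream stage testable without external data:

* ``make_bundle_phantom`` builds a diffusion-weighted volume containing
  white-matter-like bundles with known geometry.  Bundle voxels carry an
  axially symmetric anisotropic tensor oriented along the local path
  tangent; background voxels carry an isotropic tensor.  Signals follow the
  Stejskal-Tanner monoexponential model S = S0 exp(-b g^T D g), optionally
  degraded by Rician noise (magnitude of a complex Gaussian perturbation,
  sigma = S0 / snr).  Parcellation labels are placed on the bundle-end
  voxel slabs so that streamlines terminating there can be assigned to
  regions.

* ``make_cohort`` draws per-subject symmetric fiber-count matrices with
  negative-binomial edges (fiber counts are overdispersed: SD of the same
  order as the mean), plants multiplicative group effects at chosen edges,
  and derives an integer MDS-UPDRS-like clinical score linked linearly to
  chosen edge weights, floored at zero.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
spawning, so identical specs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, DWIVolume, default_scheme
from .connectome import Parcellation, region_table_from_ids
from .stats import CohortStack
from .tensor import design_matrix

__all__ = [
    "Bundle",
    "PhantomSpec",
    "CohortSpec",
    "GroundTruth",
    "simulate_dwi_signal",
    "make_bundle_phantom",
    "make_cohort",
    "default_cohort_spec",
    "DEFAULT_PLANTED_EDGES",
]

# The four planted edges of the default demo cohort, as 0-based indices into
# the packaged 39-region motor table: precentral-putamen (L), posterior
# cingulate-paracentral (R), posterior cingulate-superior frontal (R), and
# paracentral-superior frontal (L).
DEFAULT_PLANTED_EDGES: tuple[tuple[int, int], ...] = ((2, 32), (15, 17), (15, 19), (16, 18))


@dataclass(frozen=True)
class Bundle:
    """One fiber bundle: a polyline path between two labeled regions.

    ``path`` is a (k >= 2, 3) array of waypoints in voxel coordinates; the
    tangent is analytic per straight segment, so a sharp joint between
    segments produces a controlled direction change (used to test the
    tracking angle rule).  ``width`` is the cross-section diameter in voxel
    units; ``label_thickness`` is the arclength from each end whose voxels
    carry the region labels.
    """

    start_region: int
    end_region: int
    path: np.ndarray
    width: float = 1.0
    axial_diffusivity: float = 1.7e-3
    radial_diffusivity: float = 0.2e-3
    label_thickness: float = 1.0

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.path, dtype=float))
        if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 2:
            raise ValueError("bundle path must be a (k >= 2, 3) waypoint array")
        if int(self.start_region) == int(self.end_region):
            raise ValueError("bundle endpoint region ids must be distinct")
        if self.start_region <= 0 or self.end_region <= 0:
            raise ValueError("region ids must be positive (0 is background)")
        if self.width < 1.0:
            raise ValueError("cross-section width must be >= 1 voxel")
        if self.axial_diffusivity <= 0 or self.radial_diffusivity <= 0:
            raise ValueError("diffusivities must be positive")
        object.__setattr__(self, "path", p)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue and acquisition parameters of a diffusion phantom.

    ``snr`` is the S0/sigma ratio of the Rician noise; ``math.inf`` (the
    default) yields a noiseless phantom, which is the configuration used for
    exact geometric validation.
    """

    grid_dims: tuple[int, int, int]
    bundles: tuple[Bundle, ...]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    background_diffusivity: float = 0.7e-3
    s0: float = 1000.0
    snr: float = math.inf
    seed: int = 0
    scheme: AcquisitionScheme | None = None

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.grid_dims)
        if len(dims) != 3 or any(d < 4 for d in dims):
            raise ValueError("grid_dims must be three axes, each >= 4")
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be positive")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (inf for noiseless)")
        object.__setattr__(self, "grid_dims", dims)
        object.__setattr__(self, "bundles", tuple(self.bundles))


@dataclass
class GroundTruth:
    """What the generator planted, for downstream verification.

    Phantoms record per-bundle voxel sets and the expected endpoint-region
    pairs; cohorts record the planted effect edges and score edges.
    """

    bundle_voxels: list[np.ndarray] | None = None
    endpoint_pairs: list[tuple[int, int]] | None = None
    effect_edges: list[tuple[int, int, float]] | None = None
    score_edges: list[tuple[int, int, float]] | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed}
        if self.bundle_voxels is not None:
            out["bundle_voxels"] = [v.tolist() for v in self.bundle_voxels]
        if self.endpoint_pairs is not None:
            out["endpoint_pairs"] = [list(p) for p in self.endpoint_pairs]
        if self.effect_edges is not None:
            out["effect_edges"] = [list(e) for e in self.effect_edges]
        if self.score_edges is not None:
            out["score_edges"] = [list(e) for e in self.score_edges]
        return out


def simulate_dwi_signal(tensor: np.ndarray, scheme: AcquisitionScheme, s0: float) -> np.ndarray:
    """Stejskal-Tanner signal S = S0 exp(-b g^T D g), one value per scheme row.

    b=0 rows return exactly S0.  Raises on a non-symmetric or non-PSD tensor.
    """
    D = np.asarray(tensor, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    if not np.allclose(D, D.T, rtol=1e-10, atol=0.0):
        raise ValueError("tensor must be symmetric")
    evals = np.linalg.eigvalsh(D)
    if evals[0] < -1e-12 * max(1.0, abs(evals[-1])):
        raise ValueError("tensor must be positive semi-definite")
    g = scheme.gradient_directions
    b = scheme.b_values
    adc = np.einsum("ni,ij,nj->n", g, D, g)
    return float(s0) * np.exp(-b * adc)


def _voxel_centers(dims: tuple[int, int, int]) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*(np.arange(d) + 0.5 for d in dims), indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])


def _rasterize_bundle(bundle: Bundle, centers: np.ndarray):
    """Return (member mask, tangent per member, arclength per member, total length)."""
    best_d = np.full(centers.shape[0], np.inf)
    best_t = np.zeros((centers.shape[0], 3))
    best_s = np.zeros(centers.shape[0])
    cum = 0.0
    for a, b in zip(bundle.path[:-1], bundle.path[1:]):
        u = b - a
        seg_len = float(np.linalg.norm(u))
        if seg_len == 0:
            continue
        uhat = u / seg_len
        s = np.clip((centers - a) @ uhat, 0.0, seg_len)
        d = np.linalg.norm(centers - (a + s[:, None] * uhat), axis=1)
        closer = d < best_d - 1e-12
        best_d[closer] = d[closer]
        best_t[closer] = uhat
        best_s[closer] = cum + s[closer]
        cum += seg_len
    member = best_d <= bundle.width / 2.0 + 1e-9
    return member, best_t, best_s, cum


def make_bundle_phantom(spec: PhantomSpec):
    """Build (DWIVolume, Parcellation, tracking mask, GroundTruth) from a spec.

    Raises if two bundles claim the same voxel with conflicting (non-parallel)
    orientations — overlapping crossings are unsupported in this generator.
    """
    dims = spec.grid_dims
    scheme = spec.scheme if spec.scheme is not None else default_scheme()
    centers = _voxel_centers(dims)
    n_vox = centers.shape[0]

    owner = np.full(n_vox, -1, dtype=int)
    tangents = np.zeros((n_vox, 3))
    labels_flat = np.zeros(n_vox, dtype=int)
    bundle_voxel_sets: list[np.ndarray] = []
    endpoint_pairs: list[tuple[int, int]] = []

    for bi, bundle in enumerate(spec.bundles):
        member, tang, arclen, total = _rasterize_bundle(bundle, centers)
        idx = np.nonzero(member)[0]
        if idx.size == 0:
            raise ValueError(f"bundle {bi} rasterizes to no voxels; path outside grid?")
        clash = idx[owner[idx] >= 0]
        for c in clash:
            cosang = abs(float(tangents[c] @ tang[c]))
            if cosang < 1.0 - 1e-6:
                raise ValueError(
                    "overlapping bundles with conflicting orientations are unsupported"
                )
        owner[idx] = bi
        tangents[idx] = tang[idx]
        near_start = idx[arclen[idx] < bundle.label_thickness]
        near_end = idx[arclen[idx] > total - bundle.label_thickness]
        for vox_idx, rid in ((near_start, bundle.start_region), (near_end, bundle.end_region)):
            prev = labels_flat[vox_idx]
            if np.any((prev != 0) & (prev != rid)):
                raise ValueError("conflicting region labels at bundle ends")
            labels_flat[vox_idx] = rid
        coords = np.column_stack(np.unravel_index(idx, dims))
        bundle_voxel_sets.append(coords)
        endpoint_pairs.append((bundle.start_region, bundle.end_region))

    # Tensor components per voxel: D = rad*I + (ax-rad) t t^T on bundles,
    # isotropic background elsewhere.
    d6 = np.zeros((n_vox, 6))
    d6[:, :3] = spec.background_diffusivity
    on = owner >= 0
    if np.any(on):
        ax = np.array([spec.bundles[o].axial_diffusivity for o in owner[on]])
        rad = np.array([spec.bundles[o].radial_diffusivity for o in owner[on]])
        t = tangents[on]
        d6[on, 0] = rad + (ax - rad) * t[:, 0] ** 2
        d6[on, 1] = rad + (ax - rad) * t[:, 1] ** 2
        d6[on, 2] = rad + (ax - rad) * t[:, 2] ** 2
        d6[on, 3] = (ax - rad) * t[:, 0] * t[:, 1]
        d6[on, 4] = (ax - rad) * t[:, 0] * t[:, 2]
        d6[on, 5] = (ax - rad) * t[:, 1] * t[:, 2]

    X = design_matrix(scheme)
    signal = np.empty((n_vox, len(scheme)))
    signal[:, scheme.b0_mask] = spec.s0
    signal[:, scheme.dwi_mask] = spec.s0 * np.exp(-(d6 @ X.T))

    if math.isfinite(spec.snr):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
        sigma = spec.s0 / spec.snr
        re = signal + rng.normal(0.0, sigma, signal.shape)
        im = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt(re * re + im * im)

    affine = np.diag([*spec.voxel_size, 1.0])
    volume = DWIVolume(
        signal=signal.reshape(dims + (len(scheme),)),
        scheme=scheme,
        affine=affine,
        voxel_size=tuple(float(v) for v in spec.voxel_size),
    )
    labels = labels_flat.reshape(dims)
    mask = on.reshape(dims)
    region_ids = sorted({rid for pair in endpoint_pairs for rid in pair})
    parcellation = Parcellation(labels=labels, region_table=region_table_from_ids(region_ids))
    truth = GroundTruth(
        bundle_voxels=bundle_voxel_sets,
        endpoint_pairs=endpoint_pairs,
        seed=spec.seed,
    )
    return volume, parcellation, mask, truth


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group connectivity cohort.

    Edge fiber counts are negative binomial with mean ``baseline_mean`` and
    dispersion theta = ``dispersion`` (variance m + m^2/theta).  Group B's
    mean is multiplied by the planted shift at each ``effect_edges`` entry.
    The clinical score is round(score_baseline + sum(slope * weight) +
    Gaussian noise), floored at 0.
    """

    n_group_a: int = 37
    n_group_b: int = 40
    n_regions: int = 39
    baseline_mean: float = 20.0
    dispersion: float = 3.0
    effect_edges: tuple[tuple[int, int, float], ...] = ()
    score_edges: tuple[tuple[int, int, float], ...] = ()
    score_baseline: float = 0.0
    score_noise_sd: float = 4.0
    group_names: tuple[str, str] = ("SWEDD", "PD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs at least 2 subjects")
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        for i, j, _ in tuple(self.effect_edges) + tuple(self.score_edges):
            if not (0 <= i < j < self.n_regions):
                raise ValueError(f"edge ({i}, {j}) must satisfy 0 <= i < j < n_regions")
        object.__setattr__(self, "effect_edges", tuple(tuple(e) for e in self.effect_edges))
        object.__setattr__(self, "score_edges", tuple(tuple(e) for e in self.score_edges))


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The demo cohort: 37 vs 40 subjects, 39 regions, four planted edges.

    The planted edges sit at the four connections reported to separate the
    groups and track the motor score; each is increased 2.5-fold in group B
    (the PD-like group) and contributes to the score with slope 0.15.
    """
    return CohortSpec(
        effect_edges=tuple((i, j, 2.5) for i, j in DEFAULT_PLANTED_EDGES),
        score_edges=tuple((i, j, 0.15) for i, j in DEFAULT_PLANTED_EDGES),
        seed=seed,
    )


def make_cohort(spec: CohortSpec):
    """Draw a (CohortStack, GroundTruth) pair from a cohort spec."""
    R = spec.n_regions
    na, nb = spec.n_group_a, spec.n_group_b
    n = na + nb
    iu, ju = np.triu_indices(R, k=1)
    n_edges = iu.size

    edge_index = {}
    for e, (i, j) in enumerate(zip(iu, ju)):
        edge_index[(int(i), int(j))] = e

    theta = spec.dispersion
    mean_a = np.full(n_edges, spec.baseline_mean)
    mean_b = mean_a.copy()
    for i, j, shift in spec.effect_edges:
        if shift <= 0:
            raise ValueError("multiplicative shifts must be positive")
        mean_b[edge_index[(i, j)]] *= shift

    ss = np.random.SeedSequence(spec.seed)
    rng_counts, rng_score = (np.random.default_rng(s) for s in ss.spawn(2))

    def _draw(means: np.ndarray, rows: int) -> np.ndarray:
        p = theta / (theta + means)
        return rng_counts.negative_binomial(theta, p[None, :], size=(rows, n_edges))

    counts = np.vstack([_draw(mean_a, na), _draw(mean_b, nb)])

    score = np.full(n, spec.score_baseline, dtype=float)
    for i, j, slope in spec.score_edges:
        score += slope * counts[:, edge_index[(i, j)]]
    score += rng_score.normal(0.0, spec.score_noise_sd, n)
    score = np.maximum(np.rint(score), 0.0).astype(int)

    matrices = np.zeros((n, R, R), dtype=int)
    matrices[:, iu, ju] = counts
    matrices[:, ju, iu] = counts

    ga, gb = spec.group_names
    stack = CohortStack(
        matrices=matrices,
        group_labels=np.array([ga] * na + [gb] * nb),
        scores=score,
        subject_ids=[f"sub-{k + 1:03d}" for k in range(n)],
        groups=(ga, gb),
    )
    truth = GroundTruth(
        effect_edges=[tuple(e) for e in spec.effect_edges],
        score_edges=[tuple(e) for e in spec.score_edges],
        seed=spec.seed,
    )
    return stack, truth
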