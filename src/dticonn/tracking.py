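"""FACT deterministic streamline tractography.

Fiber Assignment by Continuous Tracking propagates a line from the center
of each seed voxel along the voxel's principal eigenvector, advancing to
the exact exit point of the current voxel (ray-box intersection with the
voxel faces) and adopting the next voxel's eigenvector there.  Eigenvectors
are sign-ambiguous, so the candidate direction is flipped when needed to
keep a non-negative dot product with the incoming direction.  A half-track
terminates when the next voxel leaves the grid or mask, is invalid in the
field, or the direction change exceeds the angle threshold (default 60
degrees); two half-tracks launched along +e1 and -e1 are concatenated.

Coordinates are voxel-space throughout: voxel (i, j, k) spans
[i, i+1) x [j, j+1) x [k, k+1), 0-based.  World coordinates enter only at
export through the volume affine.  The tracking mask is dilated with
26-connectivity to admit the immediate neighbors of the masked tissue, but
only voxels with a valid fitted tensor can be entered or seeded.

The whole procedure contains no randomness: identical inputs give
bit-identical streamlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation

from .tensor import TensorField

__all__ = ["TrackingParams", "Streamline", "propagate_from_seed", "track_fact"]


@dataclass(frozen=True)
class TrackingParams:
    """Tunable FACT parameters.

    angle_threshold_deg : maximum direction change between voxels, degrees.
    max_steps : cap on voxel transitions per half-track.
    mask_dilation_voxels : 26-connected dilation of the tracking mask,
        realizing "the tissue and its neighbors".
    step_epsilon : nudge (voxel units) applied across voxel boundaries to
        resolve face/edge/corner hits.
    """

    angle_threshold_deg: float = 60.0
    max_steps: int = 10_000
    mask_dilation_voxels: int = 1
    step_epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 < self.angle_threshold_deg < 180.0):
            raise ValueError("angle_threshold_deg must lie in (0, 180)")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.mask_dilation_voxels < 0:
            raise ValueError("mask_dilation_voxels must be >= 0")
        if self.step_epsilon <= 0:
            raise ValueError("step_epsilon must be positive")


@dataclass
class Streamline:
    """Ordered polyline in voxel coordinates plus the voxels it visited."""

    points: np.ndarray  # (n_points, 3) float, voxel space
    voxel_path: np.ndarray  # (n_voxels, 3) int, consecutive 26-neighbors

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def endpoint_voxels(self) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
        a = tuple(int(v) for v in self.voxel_path[0])
        b = tuple(int(v) for v in self.voxel_path[-1])
        return a, b


def _exit_point(pos: np.ndarray, direction: np.ndarray, voxel: np.ndarray) -> np.ndarray:
    """Intersection of the ray pos + t*direction with the faces of ``voxel``."""
    t_exit = np.inf
    for a in range(3):
        d = direction[a]
        if d > 0:
            t = (voxel[a] + 1.0 - pos[a]) / d
        elif d < 0:
            t = (voxel[a] - pos[a]) / d
        else:
            continue
        if t < t_exit:
            t_exit = t
    return pos + t_exit * direction


def _half_track(
    seed: np.ndarray,
    direction: np.ndarray,
    field: TensorField,
    mask: np.ndarray,
    params: TrackingParams,
):
    dims = field.grid_shape
    cos_thr = np.cos(np.deg2rad(params.angle_threshold_deg))
    eps = params.step_epsilon
    cur = seed.copy()
    pos = seed + 0.5
    d = direction.astype(float)
    points = [pos]
    voxels = [cur.copy()]
    for _ in range(params.max_steps):
        exit_pos = _exit_point(pos, d, cur)
        probe = exit_pos + eps * d
        nxt = np.floor(probe).astype(int)
        stop = (
            np.any(nxt < 0)
            or np.any(nxt >= dims)
            or not mask[tuple(nxt)]
            or not field.valid[tuple(nxt)]
        )
        if not stop:
            cand = field.principal_eigenvector[tuple(nxt)]
            if float(cand @ d) < 0.0:
                cand = -cand
            stop = float(cand @ d) < cos_thr - 1e-12
        if stop:
            points.append(exit_pos - eps * d)  # stay inside the last voxel
            return points, voxels
        points.append(exit_pos)
        voxels.append(nxt)
        pos = probe
        cur = nxt
        d = cand
    return points, voxels


def propagate_from_seed(
    seed_voxel: tuple[int, int, int],
    field: TensorField,
    mask: np.ndarray,
    params: TrackingParams | None = None,
) -> Streamline | None:
    """Launch a bidirectional FACT track from the center of ``seed_voxel``.

    Returns ``None`` when the seed is outside the mask, invalid in the
    field, or both half-tracks terminate without leaving the seed voxel.
    Raises ``IndexError`` for a seed outside the grid.
    """
    params = params or TrackingParams()
    seed = np.asarray(seed_voxel, dtype=int)
    dims = field.grid_shape
    if np.any(seed < 0) or np.any(seed >= dims):
        raise IndexError(f"seed voxel {seed_voxel!r} outside grid {dims}")
    if not mask[tuple(seed)] or not field.valid[tuple(seed)]:
        return None

    e1 = field.principal_eigenvector[tuple(seed)]
    fwd_pts, fwd_vox = _half_track(seed, e1, field, mask, params)
    bwd_pts, bwd_vox = _half_track(seed, -e1, field, mask, params)
    if len(fwd_vox) == 1 and len(bwd_vox) == 1:
        return None  # both halves terminated immediately

    points = np.array(bwd_pts[::-1][:-1] + fwd_pts)
    voxel_path = np.array(bwd_vox[::-1][:-1] + fwd_vox, dtype=int)
    return Streamline(points=points, voxel_path=voxel_path)


def track_fact(
    field: TensorField,
    mask: np.ndarray,
    params: TrackingParams | None = None,
) -> list[Streamline]:
    """Whole-volume FACT: every voxel of the (dilated) mask is a seed.

    The mask is first dilated ``mask_dilation_voxels`` times with a
    26-connected structuring element; seeds are enumerated in lexicographic
    voxel order, so output order is deterministic.
    """
    params = params or TrackingParams()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != field.grid_shape:
        raise ValueError("mask grid does not match tensor field grid")
    if params.mask_dilation_voxels > 0:
        mask = binary_dilation(
            mask,
            structure=np.ones((3, 3, 3), dtype=bool),
            iterations=params.mask_dilation_voxels,
        )
    streamlines = []
    for seed in np.argwhere(mask):
        sl = propagate_from_seed(tuple(seed), field, mask, params)
        if sl is not None:
            streamlines.append(sl)
    return streamlines
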