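"""Diffusion acquisition scheme and 4-D diffusion-weighted volume containers.

The default scheme mirrors a common single-shell clinical protocol:
b = 1000 s/mm^2 over 64 gradient directions plus one unweighted (b0)
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionScheme", "DWIVolume", "default_scheme"]

_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-measurement b-values (s/mm^2) and unit gradient directions.

    Directions of b=0 rows are ignored and may be zero vectors.  Directions
    of diffusion-weighted rows must be unit-norm within 1e-6.
    """

    b_values: np.ndarray
    gradient_directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float).ravel()
        g = np.asarray(self.gradient_directions, dtype=float)
        if g.ndim != 2 or g.shape[1] != 3:
            raise ValueError("gradient_directions must have shape (n, 3)")
        if b.shape[0] != g.shape[0]:
            raise ValueError("b_values and gradient_directions length mismatch")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(b == 0):
            raise ValueError("scheme needs at least one b=0 measurement")
        dw = b > 0
        norms = np.linalg.norm(g[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
            raise ValueError("diffusion-weighted gradient directions must be unit-norm")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "gradient_directions", g)

    def __len__(self) -> int:
        return self.b_values.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.b_values > 0


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, well-spread unit directions (spherical Fibonacci)."""
    i = np.arange(n)
    z = (2.0 * i + 1.0) / n - 1.0
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def default_scheme(n_directions: int = 64, b_value: float = 1000.0) -> AcquisitionScheme:
    """Single-shell scheme: one b0 followed by ``n_directions`` weighted rows."""
    dirs = _fibonacci_hemisphere(n_directions)
    g = np.vstack([np.zeros(3), dirs])
    b = np.concatenate([[0.0], np.full(n_directions, float(b_value))])
    return AcquisitionScheme(b, g)


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal with its scheme and spatial metadata.

    ``signal`` is indexed (x, y, z, measurement); ``affine`` maps voxel
    indices to world mm; ``voxel_size`` is mm per axis.
    """

    signal: np.ndarray
    scheme: AcquisitionScheme
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 4:
            raise ValueError("signal must be a 4-D array (x, y, z, measurement)")
        if sig.shape[3] != len(self.scheme):
            raise ValueError("4th dimension must match scheme length")
        if np.any(sig < 0):
            raise ValueError("signal must be non-negative")
        self.signal = sig
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]
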