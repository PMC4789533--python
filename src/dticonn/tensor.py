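"""Per-voxel diffusion tensor estimation and eigen-structure.

The diffusion tensor D is a 3x3 symmetric positive semi-definite matrix
(mm^2/s) relating the measured signal to the acquisition through the
monoexponential model S = S0 * exp(-b g^T D g).  Fitting is ordinary
log-linear least squares over the six unique tensor components: with
y = -ln(S/S0) and design row b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz,
2 gy gz], the system y = X d is solved per voxel.  This estimator is
deterministic and closed-form; it is adequate at moderate SNR and is the
conventional baseline before weighted or nonlinear variants.

Eigenvalues are sorted descending (lambda1 >= lambda2 >= lambda3); negative
eigenvalues (possible under noise) are clamped to zero and the voxel is
flagged low-confidence rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionScheme, DWIVolume

__all__ = [
    "TensorField",
    "fit_tensor_loglinear",
    "principal_direction",
    "fractional_anisotropy",
    "design_matrix",
    "tensor_from_components",
]

_EIG_TIE_TOL = 1e-12
_SIGNAL_FLOOR_FRAC = 1e-6  # signal floor before log: max(S, 1e-6 * S0)


@dataclass
class TensorField:
    """Voxel grid of symmetric diffusion tensors with eigen-decomposition.

    Attributes
    ----------
    tensor : (X, Y, Z, 3, 3) symmetric tensors, mm^2/s.
    eigenvalues : (X, Y, Z, 3) sorted descending, clamped at 0.
    principal_eigenvector : (X, Y, Z, 3) unit vector with sign convention
        "first component of magnitude > 1e-12 is positive".
    valid : (X, Y, Z) bool; True where a tensor was fitted.
    low_confidence : (X, Y, Z) bool; clamped eigenvalues or a degenerate
        lambda1 ~ lambda2 tie.  Tracking treats these like any valid voxel.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    principal_eigenvector: np.ndarray
    valid: np.ndarray
    low_confidence: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.valid.shape


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Rows b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] for b > 0."""
    g = scheme.gradient_directions[scheme.dwi_mask]
    b = scheme.b_values[scheme.dwi_mask]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return b[:, None] * np.column_stack(
        [gx * gx, gy * gy, gz * gz, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def tensor_from_components(d: np.ndarray) -> np.ndarray:
    """(..., 6) components [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> (..., 3, 3)."""
    d = np.asarray(d, dtype=float)
    t = np.empty(d.shape[:-1] + (3, 3), dtype=float)
    t[..., 0, 0] = d[..., 0]
    t[..., 1, 1] = d[..., 1]
    t[..., 2, 2] = d[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = d[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = d[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = d[..., 5]
    return t


def _sign_convention(vecs: np.ndarray) -> np.ndarray:
    """Flip vectors so the first component with |v_i| > 1e-12 is positive."""
    v = vecs
    s = np.where(
        np.abs(v[..., 0]) > _EIG_TIE_TOL,
        np.sign(v[..., 0]),
        np.where(
            np.abs(v[..., 1]) > _EIG_TIE_TOL,
            np.sign(v[..., 1]),
            np.where(v[..., 2] >= 0, 1.0, -1.0),
        ),
    )
    return v * s[..., None]


def fit_tensor_loglinear(volume: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Fit a diffusion tensor per masked voxel by log-linear least squares.

    S0 is the mean of the b=0 measurements per voxel.  Signals below
    1e-6 * S0 are floored before the log.  Raises ``ValueError`` if the
    scheme has no diffusion-weighted rows or its design matrix has rank < 6.
    """
    scheme = volume.scheme
    if not np.any(scheme.dwi_mask):
        raise ValueError("scheme has only b=0 measurements; tensor fit impossible")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError(
            "degenerate scheme: design matrix rank < 6 "
            "(need >= 6 non-collinear gradient directions)"
        )

    shape = volume.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != shape:
            raise ValueError("mask grid does not match volume grid")

    sig = volume.signal[mask]  # (n_vox, n_meas)
    s0 = sig[:, scheme.b0_mask].mean(axis=1)
    fit_ok = s0 > 0
    s0_safe = np.where(fit_ok, s0, 1.0)
    dwi = sig[:, scheme.dwi_mask]
    floor = _SIGNAL_FLOOR_FRAC * s0_safe[:, None]
    y = -np.log(np.maximum(dwi, floor) / s0_safe[:, None])

    pinv = np.linalg.pinv(X)  # (6, n_dwi)
    comps = y @ pinv.T  # (n_vox, 6)
    tensors = tensor_from_components(comps)

    vals, vecs = np.linalg.eigh(tensors)  # ascending
    vals = vals[:, ::-1]
    vecs = vecs[:, :, ::-1]  # column k -> k-th largest

    clamped = vals[:, 2] < 0
    vals = np.maximum(vals, 0.0)
    tie = np.abs(vals[:, 0] - vals[:, 1]) < _EIG_TIE_TOL
    e1 = _sign_convention(np.ascontiguousarray(vecs[:, :, 0]))

    field = TensorField(
        tensor=np.zeros(shape + (3, 3)),
        eigenvalues=np.zeros(shape + (3,)),
        principal_eigenvector=np.zeros(shape + (3,)),
        valid=np.zeros(shape, dtype=bool),
        low_confidence=np.zeros(shape, dtype=bool),
    )
    field.tensor[mask] = tensors
    field.eigenvalues[mask] = vals
    field.principal_eigenvector[mask] = e1
    valid = np.zeros(shape, dtype=bool)
    valid[mask] = fit_ok
    field.valid = valid
    low = np.zeros(shape, dtype=bool)
    low[mask] = clamped | tie
    field.low_confidence = low
    return field


def principal_direction(field: TensorField, voxel: tuple[int, int, int]) -> np.ndarray:
    """Principal eigenvector e1 at ``voxel`` under the fixed sign convention.

    Callers re-orient the sign per tracking context.  Raises on voxels
    outside the grid or not valid in the field.
    """
    i, j, k = (int(v) for v in voxel)
    shape = field.grid_shape
    if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
        raise IndexError(f"voxel {voxel!r} outside grid {shape}")
    if not field.valid[i, j, k]:
        raise ValueError(f"voxel {voxel!r} is not valid in the tensor field")
    return field.principal_eigenvector[i, j, k].copy()


def fractional_anisotropy(field: TensorField) -> np.ndarray:
    """FA map: sqrt(1/2) * sqrt(sum of squared eigenvalue gaps) / ||lambda||.

    Zero where all eigenvalues vanish or the voxel is invalid.  FA is 0 for
    isotropic tensors and approaches 1 in the stick limit.
    """
    lam = field.eigenvalues
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = np.sqrt(0.5) * np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    den = np.sqrt(l1 * l1 + l2 * l2 + l3 * l3)
    fa = np.zeros_like(den)
    nz = den > 0
    fa[nz] = num[nz] / den[nz]
    fa[~field.valid] = 0.0
    return np.clip(fa, 0.0, 1.0)
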