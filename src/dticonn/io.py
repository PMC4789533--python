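"""File I/O: NIfTI volumes, FSL bvals/bvecs, TRK streamlines, CSV/TSV tables.

Conventions: DWI volumes are NIfTI 4-D with the acquisition in FSL text
files (``bvals`` 1 x N, ``bvecs`` 3 x N; the transposed N x 3 layout is
auto-detected).  Connectivity matrices are CSV with region names as header
row and column.  Cohorts are a directory of per-subject matrix CSVs plus a
``subjects.csv`` (subject_id, group, score).  Streamlines export to
TrackVis TRK with header geometry taken from the source volume, or to a
plain-text dump for inspection and testing.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme, DWIVolume
from .connectome import ConnectivityMatrix, Parcellation
from .stats import CohortStack
from .tracking import Streamline

__all__ = [
    "save_nifti",
    "load_nifti",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "load_dwi",
    "save_dwi",
    "write_trk",
    "read_trk",
    "write_streamlines_text",
    "read_streamlines_text",
    "write_matrix_csv",
    "read_matrix_csv",
    "write_cohort",
    "load_cohort",
    "load_region_table",
    "write_ground_truth",
]

_BVEC_NORM_TOL = 1e-3


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def read_bvals_bvecs(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL-style whitespace tables; bvecs 3 x N or N x 3 auto-detected.

    Diffusion-weighted columns with norm within 1e-3 of 1 are renormalized
    with a warning; larger deviations raise.
    """
    b = np.loadtxt(str(bvals_path)).ravel()
    g = np.atleast_2d(np.loadtxt(str(bvecs_path)))
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape[1] != 3:
        if g.shape[0] == 3:  # ambiguous 3x3 stays as given (rows = measurements)
            pass
        else:
            raise ValueError(f"bvecs shape {g.shape} is neither 3xN nor Nx3")
    if g.shape[0] != b.shape[0]:
        raise ValueError("bvals and bvecs disagree on the number of measurements")
    dw = b > 0
    norms = np.linalg.norm(g[dw], axis=1)
    off = np.abs(norms - 1.0)
    if np.any(off > _BVEC_NORM_TOL):
        raise ValueError("bvec columns deviate from unit norm by more than 1e-3")
    if np.any(off > 1e-12):
        warnings.warn("renormalizing bvec columns to unit norm", stacklevel=2)
        g = g.copy()
        g[dw] = g[dw] / norms[:, None]
    return b, g


def write_bvals_bvecs(scheme: AcquisitionScheme, bvals_path, bvecs_path) -> None:
    np.savetxt(str(bvals_path), scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), scheme.gradient_directions.T, fmt="%.17g")


def load_dwi(dwi_path, bvals_path, bvecs_path) -> DWIVolume:
    data, affine = load_nifti(dwi_path)
    if data.ndim != 4:
        raise ValueError("DWI NIfTI must be 4-D")
    b, g = read_bvals_bvecs(bvals_path, bvecs_path)
    if data.shape[3] != b.shape[0]:
        raise ValueError("signal 4th dimension does not match the scheme length")
    voxel_size = tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return DWIVolume(
        signal=data,
        scheme=AcquisitionScheme(b, g),
        affine=affine,
        voxel_size=voxel_size,
    )


def save_dwi(volume: DWIVolume, dwi_path, bvals_path, bvecs_path) -> None:
    save_nifti(volume.signal, volume.affine, dwi_path)
    write_bvals_bvecs(volume.scheme, bvals_path, bvecs_path)


def _corner_affine(affine: np.ndarray) -> np.ndarray:
    """Voxel-space (corner-origin, centers at i+0.5) -> RAS mm affine."""
    shift = np.eye(4)
    shift[:3, 3] = -0.5
    return np.asarray(affine, dtype=float) @ shift


def write_trk(
    streamlines: list[Streamline],
    path,
    affine: np.ndarray,
    voxel_size: tuple[float, float, float],
    dimensions: tuple[int, int, int],
) -> None:
    """Export streamlines to TrackVis TRK with the source volume's geometry."""
    tractogram = nib.streamlines.Tractogram(
        [sl.points.astype(np.float32) for sl in streamlines],
        affine_to_rasmm=_corner_affine(affine).astype(np.float32),
    )
    header = {
        "voxel_sizes": np.asarray(voxel_size, dtype=np.float32),
        "dimensions": np.asarray(dimensions, dtype=np.int16),
        "voxel_to_rasmm": np.asarray(affine, dtype=np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.trk.TrkFile(tractogram, header=header).save(str(path))


def read_trk(path) -> list[np.ndarray]:
    """Load TRK and return point arrays in voxel space (centers at i+0.5)."""
    trk = nib.streamlines.load(str(path))
    inv = np.linalg.inv(_corner_affine(trk.header["voxel_to_rasmm"]))
    tg = trk.tractogram.apply_affine(inv, lazy=False)
    return [np.asarray(s, dtype=float) for s in tg.streamlines]


def write_streamlines_text(streamlines: list[Streamline], path) -> None:
    """Plain-text dump: blocks of x y z lines separated by blank lines."""
    with open(path, "w") as fh:
        for sl in streamlines:
            for p in sl.points:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
            fh.write("\n")


def read_streamlines_text(path) -> list[Streamline]:
    blocks: list[list[list[float]]] = [[]]
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                if blocks[-1]:
                    blocks.append([])
                continue
            blocks[-1].append([float(v) for v in line.split()])
    out = []
    for block in blocks:
        if not block:
            continue
        pts = np.asarray(block)
        out.append(Streamline(points=pts, voxel_path=np.floor(pts).astype(int)))
    return out


def write_matrix_csv(matrix: ConnectivityMatrix, path) -> None:
    matrix.to_frame().to_csv(path)


def read_matrix_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("connectivity CSV must be square")
    return df


def load_region_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_region_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_cohort(stack: CohortStack, directory) -> None:
    """One CSV per subject plus subjects.csv (subject_id, group, score)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = stack.region_names or [f"r{k}" for k in range(stack.n_regions)]
    for k, sid in enumerate(stack.subject_ids):
        pd.DataFrame(stack.matrices[k], index=names, columns=names).to_csv(
            directory / f"{sid}.csv"
        )
    pd.DataFrame(
        {
            "subject_id": stack.subject_ids,
            "group": stack.group_labels,
            "score": stack.scores,
        }
    ).to_csv(directory / "subjects.csv", index=False)


def load_cohort(directory) -> CohortStack:
    directory = Path(directory)
    subjects = pd.read_csv(directory / "subjects.csv")
    matrices = []
    names = None
    for sid in subjects["subject_id"]:
        df = read_matrix_csv(directory / f"{sid}.csv")
        if names is None:
            names = df.index.tolist()
        matrices.append(df.to_numpy())
    groups = tuple(pd.unique(subjects["group"]))
    if len(groups) != 2:
        raise ValueError("subjects.csv must contain exactly two groups")
    return CohortStack(
        matrices=np.asarray(matrices),
        group_labels=subjects["group"].to_numpy(),
        scores=subjects["score"].to_numpy(),
        subject_ids=subjects["subject_id"].astype(str).tolist(),
        groups=groups,  # type: ignore[arg-type]
        region_names=names,
    )


def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)


def write_parcellation(parcellation: Parcellation, labels_path, table_path, affine) -> None:
    save_nifti(parcellation.labels.astype(np.int16), affine, labels_path)
    write_region_table(parcellation.region_table, table_path)
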