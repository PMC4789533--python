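"""Fiber-count connectivity matrices over a parcellation.

A streamline contributes one count to the unordered pair of regions that
contain its two terminal points; streamlines with a background endpoint or
both endpoints in one region are discarded.  The resulting region x region
matrix is symmetric with a zero diagonal, and entries supported by fewer
than ``min_fibers`` streamlines (default 5) are zeroed, as a very small
fiber count is an unstable tractography result.  The network model is
undirected and weighted by fiber count.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .tracking import Streamline

__all__ = [
    "Parcellation",
    "ConnectivityMatrix",
    "assign_endpoints",
    "build_connectivity_matrix",
    "default_region_table",
    "region_table_from_ids",
]

_REGION_COLUMNS = ["id", "name", "hemisphere"]


def default_region_table() -> pd.DataFrame:
    """The packaged motor-related region table: 19 bilateral pairs + brainstem.

    Columns: id, name, hemisphere, cluster.  The clusters group the regions
    into motor/premotor cortex, DLPFC, cingulate motor area, SMA, parietal
    lobe, subcortical nuclei, and brainstem.
    """
    with resources.files("dticonn.data").joinpath("motor_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def region_table_from_ids(region_ids) -> pd.DataFrame:
    """Minimal region table for synthetic parcellations (phantoms)."""
    ids = sorted(int(r) for r in region_ids)
    return pd.DataFrame(
        {"id": ids, "name": [f"region_{r}" for r in ids], "hemisphere": ["NA"] * len(ids)}
    )


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus an ordered region table."""

    labels: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer volume")
        missing = set(_REGION_COLUMNS) - set(self.region_table.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        ids = self.region_table["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(int(i) for i in ids)
        if unknown:
            raise ValueError(f"label values missing from region table: {sorted(unknown)}")

    @property
    def region_ids(self) -> np.ndarray:
        return self.region_table["id"].to_numpy(dtype=int)

    @property
    def region_names(self) -> list[str]:
        return self.region_table["name"].tolist()


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region fiber-count matrix, region_table order."""

    weights: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if w.shape[0] != len(self.region_table):
            raise ValueError("matrix size must match region table length")
        if np.any(w < 0) or not np.array_equal(w, w.T) or np.any(np.diag(w) != 0):
            raise ValueError("weights must be symmetric, non-negative, zero-diagonal")
        self.weights = w

    def to_frame(self) -> pd.DataFrame:
        names = self.region_table["name"].tolist()
        return pd.DataFrame(self.weights, index=names, columns=names)


def assign_endpoints(
    streamline: Streamline, parcellation: Parcellation
) -> tuple[int, int] | None:
    """Unordered region pair containing the streamline's terminal points.

    Returns ``None`` for a background endpoint or both endpoints in a single
    region (self-loops are excluded).  Raises if a terminal point falls
    outside the parcellation grid, which would violate the tracking contract.
    """
    labels = parcellation.labels
    pair = []
    for point in (streamline.points[0], streamline.points[-1]):
        vox = np.floor(point).astype(int)
        if np.any(vox < 0) or np.any(vox >= labels.shape):
            raise ValueError(f"streamline endpoint {point} outside the grid")
        pair.append(int(labels[tuple(vox)]))
    a, b = pair
    if a == 0 or b == 0 or a == b:
        return None
    return (a, b) if a < b else (b, a)


def build_connectivity_matrix(
    streamlines: list[Streamline],
    parcellation: Parcellation,
    min_fibers: int = 5,
) -> ConnectivityMatrix:
    """Count retained endpoint pairs per region pair and threshold.

    Entries supported by fewer than ``min_fibers`` streamlines are set to 0;
    an entry of exactly ``min_fibers`` is retained.
    """
    if min_fibers < 0:
        raise ValueError("min_fibers must be >= 0")
    table = parcellation.region_table
    index = {int(rid): k for k, rid in enumerate(table["id"])}
    n = len(table)
    weights = np.zeros((n, n), dtype=int)
    for sl in streamlines:
        pair = assign_endpoints(sl, parcellation)
        if pair is None:
            continue
        a, b = (index[p] for p in pair)
        weights[a, b] += 1
        weights[b, a] += 1
    weights[weights < min_fibers] = 0
    return ConnectivityMatrix(weights=weights, region_table=table)
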