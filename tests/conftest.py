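import numpy as np
import pytest

from dticonn import (
    Bundle,
    PhantomSpec,
    TensorField,
    default_scheme,
    fit_tensor_loglinear,
    make_bundle_phantom,
)
from dticonn.stats import CohortStack


@pytest.fixture(scope="session")
def scheme64():
    return default_scheme()


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight bundle: 50 voxels along x, labels on the end slabs."""
    bundle = Bundle(
        start_region=1,
        end_region=2,
        path=np.array([[3.5, 3.5, 3.5], [52.5, 3.5, 3.5]]),
    )
    spec = PhantomSpec(grid_dims=(56, 7, 7), bundles=(bundle,))
    volume, parcellation, mask, truth = make_bundle_phantom(spec)
    field = fit_tensor_loglinear(volume, mask)
    return {
        "spec": spec,
        "volume": volume,
        "parcellation": parcellation,
        "mask": mask,
        "truth": truth,
        "field": field,
    }


@pytest.fixture(scope="session")
def elbow_phantom():
    """Noiseless 90-degree sharp bend between the same two labeled regions."""
    bundle = Bundle(
        start_region=1,
        end_region=2,
        path=np.array([[3.5, 3.5, 3.5], [20.5, 3.5, 3.5], [20.5, 20.5, 3.5]]),
    )
    spec = PhantomSpec(grid_dims=(26, 26, 7), bundles=(bundle,))
    volume, parcellation, mask, truth = make_bundle_phantom(spec)
    field = fit_tensor_loglinear(volume, mask)
    return {
        "spec": spec,
        "volume": volume,
        "parcellation": parcellation,
        "mask": mask,
        "truth": truth,
        "field": field,
    }


def uniform_field(dims, direction, valid=None) -> TensorField:
    """Tensor field with one principal direction everywhere (for tracking tests)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    e1 = np.broadcast_to(d, dims + (3,)).copy()
    vals = np.zeros(dims + (3,))
    vals[..., 0] = 1.7e-3
    vals[..., 1:] = 0.2e-3
    if valid is None:
        valid = np.ones(dims, dtype=bool)
    return TensorField(
        tensor=np.zeros(dims + (3, 3)),
        eigenvalues=vals,
        principal_eigenvector=e1,
        valid=valid,
        low_confidence=np.zeros(dims, dtype=bool),
    )


def one_edge_stack(values, labels, groups=("A", "B")) -> CohortStack:
    """Two-region cohort whose single edge carries ``values`` per subject."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    m = np.zeros((n, 2, 2))
    m[:, 0, 1] = values
    m[:, 1, 0] = values
    return CohortStack(
        matrices=m,
        group_labels=np.asarray(labels),
        scores=np.zeros(n, dtype=int),
        subject_ids=[f"s{i}" for i in range(n)],
        groups=groups,
    )
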