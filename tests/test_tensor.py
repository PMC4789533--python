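"""Tensor fitting, eigen-structure, and fractional anisotropy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dticonn import (
    AcquisitionScheme,
    DWIVolume,
    TensorField,
    fit_tensor_loglinear,
    fractional_anisotropy,
    principal_direction,
    simulate_dwi_signal,
)


def _volume_from_tensor(D, scheme, s0=1000.0, dims=(2, 2, 2)):
    sig = simulate_dwi_signal(D, scheme, s0)
    return DWIVolume(signal=np.tile(sig, dims + (1,)), scheme=scheme)


def _field_from_eigenvalues(lam) -> TensorField:
    lam = np.asarray(lam, dtype=float).reshape(1, 1, 1, 3)
    return TensorField(
        tensor=np.zeros((1, 1, 1, 3, 3)),
        eigenvalues=lam,
        principal_eigenvector=np.broadcast_to([1.0, 0.0, 0.0], (1, 1, 1, 3)).copy(),
        valid=np.ones((1, 1, 1), dtype=bool),
        low_confidence=np.zeros((1, 1, 1), dtype=bool),
    )


def _rotation_z(deg):
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


class TestSignalModel:
    def test_b0_returns_s0_exactly(self, scheme64):
        sig = simulate_dwi_signal(np.diag([3e-3, 2e-3, 1e-3]), scheme64, 500.0)
        assert sig[scheme64.b0_mask] == pytest.approx(500.0, abs=0)

    def test_isotropic_attenuation(self):
        scheme = AcquisitionScheme([0.0, 1000.0], [[0, 0, 0], [1.0, 0.0, 0.0]])
        sig = simulate_dwi_signal(0.7e-3 * np.eye(3), scheme, 1000.0)
        assert sig[1] == pytest.approx(1000.0 * np.exp(-0.7), rel=1e-12)

    def test_anisotropic_attenuation_along_y(self):
        scheme = AcquisitionScheme([0.0, 1000.0], [[0, 0, 0], [0.0, 1.0, 0.0]])
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        assert simulate_dwi_signal(D, scheme, 1.0)[1] == pytest.approx(np.exp(-0.3), rel=1e-12)

    def test_rejects_nonsymmetric_tensor(self, scheme64):
        D = np.diag([1.0e-3] * 3)
        D[0, 1] = 5e-4
        with pytest.raises(ValueError, match="symmetric"):
            simulate_dwi_signal(D, scheme64, 1.0)

    def test_rejects_non_unit_gradient(self):
        with pytest.raises(ValueError, match="unit-norm"):
            AcquisitionScheme([0.0, 1000.0], [[0, 0, 0], [1.0, 1.0, 0.0]])


class TestLogLinearFit:
    def test_noiseless_round_trip(self, scheme64):
        D = np.diag([1.5e-3, 0.3e-3, 0.3e-3])
        field = fit_tensor_loglinear(_volume_from_tensor(D, scheme64))
        rel = np.abs(field.tensor[0, 0, 0] - D).max() / D.max()
        assert rel < 1e-6
        assert field.valid.all()

    def test_isotropic_eigenvalues_preserved(self, scheme64):
        field = fit_tensor_loglinear(_volume_from_tensor(0.7e-3 * np.eye(3), scheme64))
        assert field.eigenvalues[0, 0, 0] == pytest.approx([0.7e-3] * 3, rel=1e-9)

    def test_five_direction_scheme_raises_rank_error(self):
        # 5 directions give a rank-deficient 6-unknown system
        dirs = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 0, 1]], dtype=float
        )
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        scheme = AcquisitionScheme(
            [0.0] + [1000.0] * 5, np.vstack([np.zeros(3), dirs])
        )
        vol = _volume_from_tensor(np.diag([1.0e-3] * 3), scheme)
        with pytest.raises(ValueError, match="rank"):
            fit_tensor_loglinear(vol)

    def test_all_b0_scheme_raises(self):
        scheme = AcquisitionScheme([0.0, 0.0], np.zeros((2, 3)))
        vol = DWIVolume(signal=np.full((2, 2, 2, 2), 100.0), scheme=scheme)
        with pytest.raises(ValueError, match="b=0"):
            fit_tensor_loglinear(vol)

    def test_rotation_equivariance(self, scheme64):
        rng = np.random.default_rng(11)
        D = np.diag([1.6e-3, 0.4e-3, 0.2e-3])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = q @ D @ q.T
        f_rot = fit_tensor_loglinear(_volume_from_tensor(rotated, scheme64))
        f_ref = fit_tensor_loglinear(_volume_from_tensor(D, scheme64))
        expect = q @ f_ref.tensor[0, 0, 0] @ q.T
        assert np.abs(f_rot.tensor[0, 0, 0] - expect).max() / D.max() < 1e-6

    def test_mask_restricts_validity(self, scheme64):
        vol = _volume_from_tensor(np.diag([1.0e-3] * 3), scheme64, dims=(3, 3, 3))
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        field = fit_tensor_loglinear(vol, mask)
        assert field.valid[1, 1, 1] and field.valid.sum() == 1


class TestPrincipalDirection:
    def test_axis_aligned_diagonal_tensor(self, scheme64):
        field = fit_tensor_loglinear(
            _volume_from_tensor(np.diag([3e-3, 2e-3, 1e-3]), scheme64)
        )
        assert principal_direction(field, (0, 0, 0)) == pytest.approx([1, 0, 0], abs=1e-9)

    def test_rotated_tensor_matches_eigen_oracle(self, scheme64):
        R = _rotation_z(30.0)
        D = R @ np.diag([3e-3, 2e-3, 1e-3]) @ R.T
        field = fit_tensor_loglinear(_volume_from_tensor(D, scheme64))
        e1 = principal_direction(field, (0, 0, 0))
        expected = R @ np.array([1.0, 0.0, 0.0])
        assert min(np.linalg.norm(e1 - expected), np.linalg.norm(e1 + expected)) < 1e-6

    def test_oblate_tie_is_flagged_and_unit(self, scheme64):
        field = fit_tensor_loglinear(
            _volume_from_tensor(np.diag([1e-3, 1e-3, 0.5e-3]), scheme64)
        )
        assert field.low_confidence[0, 0, 0]
        assert np.linalg.norm(principal_direction(field, (0, 0, 0))) == pytest.approx(1.0)

    def test_sign_convention_first_nonzero_positive(self, scheme64):
        R = _rotation_z(120.0)  # principal axis with a negative x component
        D = R @ np.diag([3e-3, 2e-3, 1e-3]) @ R.T
        field = fit_tensor_loglinear(_volume_from_tensor(D, scheme64))
        e1 = principal_direction(field, (0, 0, 0))
        nz = np.nonzero(np.abs(e1) > 1e-9)[0]
        assert e1[nz[0]] > 0

    def test_invalid_voxel_and_out_of_grid(self, scheme64):
        vol = _volume_from_tensor(np.diag([1.0e-3] * 3), scheme64)
        mask = np.zeros((2, 2, 2), dtype=bool)
        mask[0, 0, 0] = True
        field = fit_tensor_loglinear(vol, mask)
        with pytest.raises(ValueError):
            principal_direction(field, (1, 1, 1))
        with pytest.raises(IndexError):
            principal_direction(field, (5, 0, 0))


class TestFractionalAnisotropy:
    @pytest.mark.parametrize(
        "lam, expected",
        [
            ((1.0, 1.0, 1.0), 0.0),
            ((1.0, 0.0, 0.0), 1.0),
            ((3.0, 2.0, 1.0), np.sqrt(3.0 / 14.0)),
        ],
    )
    def test_closed_form_values(self, lam, expected):
        fa = fractional_anisotropy(_field_from_eigenvalues(lam))
        assert fa[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        st.tuples(
            st.floats(0.0, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0)
        )
    )
    def test_bounded_between_zero_and_one(self, lam):
        lam = tuple(sorted(lam, reverse=True))
        fa = fractional_anisotropy(_field_from_eigenvalues(lam))
        assert 0.0 <= fa[0, 0, 0] <= 1.0
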