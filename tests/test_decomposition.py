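"""Basis calibration, the per-voxel three-material solve, merging."""

import numpy as np
import pytest

from dectlung import (
    CtVolume,
    DectPair,
    DegenerateBasisError,
    MaterialBasis,
    RoiMask,
    calibrate_basis,
    decompose,
    decompose_raw,
    default_basis,
    merge_volumes,
    noncontrast_equivalent_hu,
)
from dectlung.decomposition import project_to_simplex


def pair_from(low, high, spacing=(1.0, 1.0, 1.0)):
    return DectPair(CtVolume(low, spacing), CtVolume(high, spacing))


def roi(shape, where=None):
    m = np.zeros(shape, dtype=bool)
    if where is None:
        m[:] = True
    else:
        m[where] = True
    return m


class TestCalibrateBasis:
    def test_constant_rois_give_their_values(self):
        shape = (4, 4, 2)
        low = np.full(shape, 100.0)
        high = np.full(shape, 80.0)
        low[:2], high[:2] = 400.0, 250.0  # aorta region
        low[2:], high[2:] = 60.0, 55.0  # muscle region
        aorta = RoiMask(roi(shape, np.s_[:2]), "aorta")
        muscle = RoiMask(roi(shape, np.s_[2:]), "muscle")
        basis = calibrate_basis(pair_from(low, high), aorta, muscle)
        np.testing.assert_allclose(basis.coefficients[2], [400.0, 250.0])
        np.testing.assert_allclose(basis.coefficients[1], [60.0, 55.0])

    def test_gas_row_always_minus_1000(self):
        shape = (4, 4, 2)
        rng = np.random.default_rng(0)
        basis = calibrate_basis(
            pair_from(rng.normal(300, 50, shape), rng.normal(200, 50, shape)),
            RoiMask(roi(shape, np.s_[:2]), "aorta"),
            RoiMask(roi(shape, np.s_[2:]), "muscle"),
        )
        np.testing.assert_array_equal(basis.coefficients[0], [-1000.0, -1000.0])

    def test_roi_mean_matches_summation_oracle(self):
        shape = (10, 10, 4)
        rng = np.random.default_rng(3)
        low = rng.normal(380, 25, shape)
        high = rng.normal(240, 25, shape)
        aorta_mask = roi(shape, np.s_[:5])
        muscle_mask = roi(shape, np.s_[5:])
        basis = calibrate_basis(
            pair_from(low, high), RoiMask(aorta_mask, "aorta"), RoiMask(muscle_mask, "muscle")
        )
        # independent mean: explicit sum over listed voxels
        vox = [low[i, j, k] for i, j, k in np.argwhere(aorta_mask)]
        assert basis.coefficients[2, 0] == pytest.approx(sum(vox) / len(vox), abs=1e-12)

    def test_empty_roi_rejected(self):
        shape = (4, 4, 2)
        p = pair_from(np.zeros(shape), np.zeros(shape))
        with pytest.raises(ValueError, match="empty"):
            calibrate_basis(p, RoiMask(np.zeros(shape, bool), "aorta"), RoiMask(roi(shape), "muscle"))

    def test_degenerate_basis_names_offending_pair(self):
        shape = (4, 4, 2)
        low = np.full(shape, 60.0)
        high = np.full(shape, 55.0)  # aorta indistinguishable from muscle
        with pytest.raises(DegenerateBasisError, match="soft_tissue.*iodinated_blood"):
            calibrate_basis(
                pair_from(low, high),
                RoiMask(roi(shape, np.s_[:2]), "aorta"),
                RoiMask(roi(shape, np.s_[2:]), "muscle"),
            )


class TestDecompose:
    def test_pure_material_vertices(self):
        basis = default_basis()
        shape = (3, 1, 1)
        low = basis.coefficients[:, 0].reshape(shape)
        high = basis.coefficients[:, 1].reshape(shape)
        fr = decompose(pair_from(low, high), basis, RoiMask(roi(shape), "all"))
        np.testing.assert_allclose(fr.as_stack()[:, 0, 0, 0], [1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(fr.as_stack()[:, 1, 0, 0], [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(fr.as_stack()[:, 2, 0, 0], [0, 0, 1], atol=1e-12)

    def test_round_trip_on_random_simplex(self):
        rng = np.random.default_rng(1)
        f = rng.dirichlet((1.0, 1.0, 1.0), size=1000).T.reshape(3, 10, 10, 10)
        basis = default_basis()
        hu = np.tensordot(basis.coefficients, f, axes=(0, 0))
        fr = decompose(pair_from(hu[0], hu[1]), basis, RoiMask(roi((10, 10, 10)), "all"))
        assert np.max(np.abs(fr.as_stack() - f)) <= 1e-9

    def test_fractions_sum_to_one_after_projection(self):
        rng = np.random.default_rng(2)
        shape = (20, 20, 5)
        low = rng.normal(-500, 300, shape)
        high = rng.normal(-500, 300, shape)
        fr = decompose(pair_from(low, high), default_basis(), RoiMask(roi(shape), "all"))
        total = fr.as_stack().sum(axis=0)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert np.nanmin(fr.as_stack()) >= 0.0

    def test_sentinel_outside_mask_and_residual_recorded(self):
        shape = (4, 4, 2)
        mask = roi(shape, np.s_[:2])
        fr = decompose(
            pair_from(np.full(shape, -2000.0), np.full(shape, -100.0)),
            default_basis(),
            RoiMask(mask, "half"),
        )
        assert np.isnan(fr.f_gas[~mask]).all()
        assert (fr.residual[mask] > 0).any()  # -2000 HU forces a projection

    def test_unbiased_under_gaussian_noise(self):
        """Raw (pre-projection) fraction errors have zero mean at 10 HU noise."""
        rng = np.random.default_rng(5)
        n = 20000
        f = rng.dirichlet((1.0, 1.0, 1.0), size=n).T.reshape(3, n, 1, 1)
        basis = default_basis()
        hu = np.tensordot(basis.coefficients, f, axes=(0, 0))
        hu += rng.normal(0.0, 10.0, size=hu.shape)
        raw = decompose_raw(pair_from(hu[0], hu[1]), basis, RoiMask(roi((n, 1, 1)), "all"))
        err = raw - f
        for m in range(3):
            e = err[m].ravel()
            se = e.std(ddof=1) / np.sqrt(n)
            assert abs(e.mean()) <= 3 * se

    def test_nonfinite_hu_rejected(self):
        shape = (4, 4, 2)
        low = np.zeros(shape)
        low[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            decompose(pair_from(low, np.zeros(shape)), default_basis(), RoiMask(roi(shape), "all"))

    def test_permuting_materials_permutes_maps(self):
        rng = np.random.default_rng(8)
        shape = (8, 8, 3)
        low = rng.normal(-400, 200, shape)
        high = rng.normal(-400, 200, shape)
        basis = default_basis()
        perm = [2, 0, 1]
        permuted = MaterialBasis(basis.coefficients[perm])
        a = decompose(pair_from(low, high), basis, RoiMask(roi(shape), "all")).as_stack()
        b = decompose(pair_from(low, high), permuted, RoiMask(roi(shape), "all")).as_stack()
        np.testing.assert_allclose(b, a[perm], atol=1e-10)

    def test_projection_policy_clips_and_renormalizes(self):
        raw = np.array([[1.2], [-0.3], [0.1]])
        proj, res = project_to_simplex(raw)
        np.testing.assert_allclose(proj[:, 0], [1.2 / 1.3, 0.0, 0.1 / 1.3])
        assert res[0] > 0


class TestMergeVolumes:
    def test_hand_blend(self):
        p = pair_from(np.full((1, 1, 1), -800.0), np.full((1, 1, 1), -600.0))
        assert merge_volumes(p, 0.7).data[0, 0, 0] == pytest.approx(-660.0)

    def test_boundary_weights(self):
        rng = np.random.default_rng(0)
        low, high = rng.normal(size=(2, 3, 3, 3))
        p = pair_from(low, high)
        np.testing.assert_array_equal(merge_volumes(p, 1.0).data, high)
        np.testing.assert_array_equal(merge_volumes(p, 0.0).data, low)

    def test_identical_inputs_unchanged(self):
        v = np.random.default_rng(1).normal(size=(3, 3, 3))
        np.testing.assert_allclose(merge_volumes(pair_from(v, v), 0.7).data, v)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        a_lo, a_hi, b_lo, b_hi = rng.normal(size=(4, 2, 2, 2))
        m_sum = merge_volumes(pair_from(a_lo + b_lo, a_hi + b_hi), 0.7).data
        m_parts = merge_volumes(pair_from(a_lo, a_hi), 0.7).data + merge_volumes(pair_from(b_lo, b_hi), 0.7).data
        np.testing.assert_allclose(m_sum, m_parts, atol=1e-12)

    def test_invalid_weight(self):
        p = pair_from(np.zeros((1, 1, 1)), np.zeros((1, 1, 1)))
        with pytest.raises(ValueError):
            merge_volumes(p, 1.2)


class TestNoncontrastEquivalentHu:
    @pytest.mark.parametrize(
        "gas,expected", [(0.10, -100.0), (0.50, -500.0), (0.90, -900.0), (1.0, -1000.0), (0.0, 0.0)]
    )
    def test_values(self, gas, expected):
        assert noncontrast_equivalent_hu(gas) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            noncontrast_equivalent_hu(1.1)
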