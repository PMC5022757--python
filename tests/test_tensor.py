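import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dticond import (
    EigenSystem,
    GradientScheme,
    ScalarMap,
    TensorField,
    TensorModelError,
    dec_axis_map,
    default_scheme,
    fit_tensor,
    fractional_anisotropy,
    make_limb_phantom,
    scalar_maps,
    simulate_dwi,
    tensor_eigensystem,
)
from dticond.tensor import DWIVolume

VOX = (1.0, 1.0, 1.0)


def field_from_matrix(d, shape=(2, 2, 2)):
    mats = np.broadcast_to(d, shape + (3, 3)).copy()
    return TensorField.from_matrices(mats, VOX)


def rotation_from_angles(rx, ry, rz):
    from dticond import EulerAngles, compose_rotation

    return compose_rotation(EulerAngles(rx, ry, rz))


class TestFitTensor:
    def test_noiseless_recovery_exact(self, scheme12):
        d = np.diag([1.7e-3, 0.2e-3, 0.2e-3])
        field = field_from_matrix(d)
        dwi = simulate_dwi(field, scheme12, s0=100.0)
        fit = fit_tensor(dwi)
        np.testing.assert_allclose(fit.components, field.components, atol=1e-12)

    def test_isotropic_off_diagonals_vanish(self, scheme12):
        field = field_from_matrix(1e-3 * np.eye(3))
        dwi = simulate_dwi(field, scheme12, s0=100.0)
        fit = fit_tensor(dwi)
        np.testing.assert_allclose(fit.components[..., 3:], 0.0, atol=1e-12)

    def test_rotated_tensor_recovery(self, scheme12):
        r = rotation_from_angles(25.0, -40.0, 110.0)
        d = r @ np.diag([1.5e-3, 0.6e-3, 0.3e-3]) @ r.T
        field = field_from_matrix(d)
        dwi = simulate_dwi(field, scheme12, s0=100.0)
        fit = fit_tensor(dwi)
        np.testing.assert_allclose(fit.components, field.components, atol=1e-12)

    def test_noisy_fit_median_fa_error_and_wls_oracle(self, scheme12):
        # ~1000 coherent muscle voxels at sigma = S0/50
        d = np.diag([1.7e-3, 0.2e-3, 0.2e-3])
        field = field_from_matrix(d, shape=(10, 10, 10))
        dwi = simulate_dwi(field, scheme12, s0=100.0, noise_sigma=2.0, seed=11)
        fit = fit_tensor(dwi)
        fa_fit = fractional_anisotropy(np.linalg.eigvalsh(fit.as_matrices()))
        fa_true = fractional_anisotropy(np.linalg.eigvalsh(d))
        assert np.median(np.abs(fa_fit - fa_true)) < 0.05

        # independent weighted-least-squares oracle: explicit per-voxel solve
        wls = fit_tensor(dwi, weighted=True)
        b0 = scheme12.b0_mask
        s_b0 = dwi.signal[..., b0].mean(axis=-1, keepdims=True)
        signals = np.concatenate([s_b0, dwi.signal[..., ~b0]], axis=-1)
        bv = np.concatenate([[0.0], scheme12.bvals[~b0]])
        gv = np.vstack([np.zeros(3), scheme12.bvecs[~b0]])
        rows = np.column_stack(
            [
                np.ones_like(bv),
                -bv * gv[:, 0] ** 2,
                -bv * gv[:, 1] ** 2,
                -bv * gv[:, 2] ** 2,
                -2 * bv * gv[:, 0] * gv[:, 1],
                -2 * bv * gv[:, 0] * gv[:, 2],
                -2 * bv * gv[:, 1] * gv[:, 2],
            ]
        )
        errs = []
        for idx in [(0, 0, 0), (3, 4, 5), (9, 9, 9)]:
            y = np.log(signals[idx])
            beta = np.linalg.lstsq(rows, y, rcond=None)[0]
            w = np.exp(rows @ beta) ** 2
            xw = rows * w[:, None]
            beta = np.linalg.solve(rows.T @ xw, xw.T @ y)
            fa_oracle = fractional_anisotropy(
                np.linalg.eigvalsh(
                    np.array(
                        [
                            [beta[1], beta[4], beta[5]],
                            [beta[4], beta[2], beta[6]],
                            [beta[5], beta[6], beta[3]],
                        ]
                    )
                )
            )
            fa_pkg = fractional_anisotropy(np.linalg.eigvalsh(wls.as_matrices()[idx]))
            errs.append(abs(fa_pkg - fa_oracle))
        assert max(errs) < 0.01

    def test_nonpositive_signal_voxels_excluded(self, scheme12):
        field = field_from_matrix(1e-3 * np.eye(3))
        dwi = simulate_dwi(field, scheme12, s0=100.0)
        sig = dwi.signal.copy()
        sig[0, 0, 0, 3] = 0.0
        dwi2 = DWIVolume(sig, VOX, scheme12)
        fit = fit_tensor(dwi2)
        assert not fit.valid[0, 0, 0]
        assert np.all(fit.components[0, 0, 0] == 0.0)
        assert fit.valid[1, 1, 1]

    def test_too_few_acquisitions_ill_posed(self):
        scheme = GradientScheme(
            np.array([0.0] + [800.0] * 5),
            np.vstack(
                [
                    np.zeros(3),
                    np.eye(3),
                    [[0.7071067811865476, 0.7071067811865476, 0.0]],
                    [[0.0, 0.7071067811865476, 0.7071067811865476]],
                ]
            ),
        )
        field = field_from_matrix(1e-3 * np.eye(3))
        dwi = simulate_dwi(field, scheme, s0=100.0)
        with pytest.raises(Exception, match="6 distinct|7 usable"):
            fit_tensor(dwi)


class TestEigensystem:
    def test_diagonal_case(self):
        field = field_from_matrix(np.diag([1.7e-3, 0.2e-3, 0.2e-3]), shape=(1, 1, 1))
        eig = tensor_eigensystem(field)
        np.testing.assert_allclose(
            eig.eigenvalues[0, 0, 0], [1.7e-3, 0.2e-3, 0.2e-3], atol=1e-18
        )
        np.testing.assert_allclose(np.abs(eig.e1[0, 0, 0]), [1, 0, 0], atol=1e-12)

    @given(
        rx=st.floats(-180, 180),
        ry=st.floats(-89, 89),
        rz=st.floats(-180, 180),
    )
    @settings(max_examples=50, deadline=None)
    def test_similarity_invariance(self, rx, ry, rz):
        d = np.diag([1.5e-3, 0.7e-3, 0.2e-3])
        r = rotation_from_angles(rx, ry, rz)
        eig = tensor_eigensystem(field_from_matrix(r @ d @ r.T, shape=(1, 1, 1)))
        np.testing.assert_allclose(
            eig.eigenvalues[0, 0, 0], np.diag(d), atol=1e-15
        )

    def test_eigenvalues_match_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(3, 3))
        spd = a @ a.T + 3 * np.eye(3)
        eig = tensor_eigensystem(field_from_matrix(spd, shape=(1, 1, 1)))
        # independent oracle: roots of det(D - x I) via the cubic's coefficients
        c2 = -np.trace(spd)
        c1 = 0.5 * (np.trace(spd) ** 2 - np.trace(spd @ spd))
        c0 = -np.linalg.det(spd)
        roots = np.sort(np.real(np.roots([1.0, c2, c1, c0])))[::-1]
        np.testing.assert_allclose(eig.eigenvalues[0, 0, 0], roots, atol=1e-10)

    def test_orthonormality_and_sign_convention(self, small_phantom):
        field, mask = small_phantom
        eig = tensor_eigensystem(field)
        v = eig.eigenvectors[mask.labels > 0]
        prods = np.einsum("nij,nik->njk", v, v)
        np.testing.assert_allclose(prods, np.broadcast_to(np.eye(3), prods.shape), atol=1e-10)
        # largest-magnitude component of each eigenvector is positive
        e1 = v[..., :, 0]
        idx = np.argmax(np.abs(e1), axis=-1)
        assert np.all(np.take_along_axis(e1, idx[:, None], axis=-1) > 0)

    def test_negative_eigenvalues_clamped_and_counted(self):
        field = field_from_matrix(np.diag([1e-3, 1e-4, -1e-5]), shape=(1, 1, 1))
        eig = tensor_eigensystem(field)
        assert eig.n_clamped == 1
        assert eig.eigenvalues[0, 0, 0, 2] == 0.0

    def test_nonfinite_entries_error_names_voxel(self):
        comps = np.zeros((2, 2, 2, 6))
        comps[1, 0, 1, 2] = np.nan
        with pytest.raises(TensorModelError, match=r"\(1, 0, 1\)"):
            tensor_eigensystem(TensorField(comps, VOX))


class TestScalarMaps:
    @pytest.mark.parametrize(
        "lam, fa_expected, adc_expected",
        [
            ((1e-3, 1e-3, 1e-3), 0.0, 1e-3),
            ((1.7e-3, 0.2e-3, 0.2e-3), 0.8704, 0.7e-3),
            ((1e-3, 0.0, 0.0), 1.0, 1e-3 / 3),
            ((0.0, 0.0, 0.0), 0.0, 0.0),
        ],
    )
    def test_fa_adc_values(self, lam, fa_expected, adc_expected):
        vals = np.array(lam)[None, None, None]
        eig = EigenSystem(vals, np.broadcast_to(np.eye(3), (1, 1, 1, 3, 3)).copy(), VOX)
        fa, adc = scalar_maps(eig)
        assert fa.data[0, 0, 0] == pytest.approx(fa_expected, abs=5e-5)
        assert adc.data[0, 0, 0] == pytest.approx(adc_expected, abs=1e-15)

    def test_map_ranges_on_phantom(self, small_phantom):
        field, _ = small_phantom
        fa, adc = scalar_maps(tensor_eigensystem(field))
        assert np.all(fa.data >= 0) and np.all(fa.data <= 1)
        assert np.all(adc.data >= 0)


class TestDecAxisMap:
    def test_axis_aligned_and_oblique(self):
        vecs = np.zeros((2, 1, 1, 3, 3))
        vecs[0, 0, 0] = np.eye(3)[:, [2, 0, 1]]  # e1 = z-hat
        oblique = np.full(3, 1 / np.sqrt(3))
        vecs[1, 0, 0, :, 0] = oblique
        vecs[1, 0, 0, :, 1] = [1 / np.sqrt(2), -1 / np.sqrt(2), 0]
        vecs[1, 0, 0, :, 2] = np.cross(oblique, vecs[1, 0, 0, :, 1])
        vals = np.broadcast_to([1.0, 0.5, 0.25], (2, 1, 1, 3)).copy()
        eig = EigenSystem(vals, vecs, VOX)
        fa = ScalarMap(np.array([[[0.8]], [[0.6]]]), "FA", VOX)
        amap = dec_axis_map(eig, fa)
        np.testing.assert_allclose(amap.data[0, 0, 0], [0, 0, 0.8], atol=1e-12)
        np.testing.assert_allclose(amap.data[1, 0, 0], [0.3464] * 3, atol=1e-4)

    def test_sign_invariance(self, small_phantom):
        field, _ = small_phantom
        eig = tensor_eigensystem(field)
        fa, _ = scalar_maps(eig)
        flipped = EigenSystem(eig.eigenvalues, -eig.eigenvectors, VOX)
        np.testing.assert_allclose(
            dec_axis_map(eig, fa).data, dec_axis_map(flipped, fa).data, atol=1e-15
        )

    def test_norm_identity(self, small_phantom):
        field, _ = small_phantom
        eig = tensor_eigensystem(field)
        fa, _ = scalar_maps(eig)
        amap = dec_axis_map(eig, fa)
        np.testing.assert_allclose(
            np.linalg.norm(amap.data, axis=-1), fa.data, atol=1e-12
        )

    def test_grid_mismatch_rejected(self, small_phantom):
        field, _ = small_phantom
        eig = tensor_eigensystem(field)
        fa = ScalarMap(np.zeros((2, 2, 2)), "FA", VOX)
        with pytest.raises(TensorModelError, match="does not match"):
            dec_axis_map(eig, fa)


class TestRoundTrip:
    def test_simulate_fit_eigensystem_recovers_ground_truth(self, coherent_spec, scheme12):
        field, mask = make_limb_phantom(coherent_spec)
        dwi = simulate_dwi(field, scheme12, s0=100.0)
        fit = fit_tensor(dwi, mask=mask)
        sel = mask.labels > 0
        truth = field.components[sel]
        # zero components are judged relative to the voxel's dominant component
        scale = np.abs(truth).max(axis=-1, keepdims=True)
        rel = np.abs(fit.components[sel] - truth) / np.maximum(np.abs(truth), scale)
        assert rel.max() < 1e-8
        eig_fit = tensor_eigensystem(fit)
        eig_true = tensor_eigensystem(field)
        np.testing.assert_allclose(
            eig_fit.eigenvalues[sel], eig_true.eigenvalues[sel], rtol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(eig_fit.e1[sel]), np.abs(eig_true.e1[sel]), atol=1e-8
        )
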