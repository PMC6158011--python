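import numpy as np
import pytest

from axonmatch.io_formats import ControlPointTable
from axonmatch.registration import (AffineTransform, FitError,
                                    FreeformTransform, apply_transform,
                                    bootstrap_cp_curve, fit_affine,
                                    fit_freeform, local_offset_correction,
                                    quat_to_matrix, residual_error,
                                    rotation_about_axis, transform_from_dict)
from axonmatch.skeletons import Skeleton
from conftest import random_tree


def random_affine(rng):
    axis = rng.normal(size=3)
    q = rotation_about_axis(axis, rng.uniform(0, np.pi))
    scale = rng.uniform(0.7, 1.4, size=3)
    t = rng.uniform(-50_000, 50_000, size=3)
    return AffineTransform(q, scale, t)


class TestFitAffine:
    def test_identity_on_identical_pairs(self, rng):
        pts = rng.uniform(0, 1e5, (10, 3))
        fit = fit_affine(ControlPointTable.from_arrays(pts, pts))
        np.testing.assert_allclose(fit.scale, 1.0, atol=1e-9)
        np.testing.assert_allclose(fit.translation, 0.0, atol=1e-4)
        np.testing.assert_allclose(quat_to_matrix(fit.quaternion), np.eye(3),
                                   atol=1e-9)

    def test_recovers_known_transform(self, rng):
        lm = rng.uniform(0, 1e5, (20, 3))
        truth = AffineTransform(rotation_about_axis([1, 1, 0],
                                                    np.deg2rad(25)),
                                np.array([1.2, 0.9, 1.1]),
                                np.array([5000.0, -3000, 2000]))
        fit = fit_affine(ControlPointTable.from_arrays(lm, truth.apply(lm)))
        np.testing.assert_allclose(fit.scale, truth.scale, rtol=1e-6)
        np.testing.assert_allclose(fit.quaternion, truth.quaternion,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.translation, truth.translation,
                                   rtol=1e-6, atol=1e-3)

    @pytest.mark.parametrize("seed", range(8))
    def test_noiseless_recovery_property(self, seed):
        """Any (rotation, positive anisotropic scale, translation) is
        recovered from noiseless pairs to 1e-6 relative."""
        rng = np.random.default_rng(seed)
        truth = random_affine(rng)
        lm = rng.uniform(0, 1.2e5, (20, 3))
        fit = fit_affine(ControlPointTable.from_arrays(lm, truth.apply(lm)))
        np.testing.assert_allclose(fit.matrix, truth.matrix, rtol=1e-6,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.translation, truth.translation,
                                   rtol=1e-6, atol=1e-2)

    def test_beats_isotropic_horn_on_anisotropic_data(self, rng):
        lm = rng.uniform(0, 1e5, (30, 3))
        truth = AffineTransform(rotation_about_axis([0, 1, 0], 0.4),
                                np.array([1.3, 0.8, 1.05]),
                                np.zeros(3))
        em = truth.apply(lm)
        cps = ControlPointTable.from_arrays(lm, em)
        fit = fit_affine(cps)
        # isotropic-scale Horn fit for comparison
        iso_best = np.inf
        for s in np.linspace(0.8, 1.3, 51):
            from axonmatch.registration import _horn_rigid
            q, R, t = _horn_rigid(lm * s, em)
            r = em - (lm * s) @ R.T - t
            iso_best = min(iso_best, float((r * r).sum()))
        r = em - fit.apply(lm)
        assert (r * r).sum() <= iso_best + 1e-9

    def test_too_few_pairs(self, rng):
        pts = rng.uniform(0, 1e5, (2, 3))
        with pytest.raises(FitError):
            fit_affine(ControlPointTable.from_arrays(pts, pts))

    def test_collinear_rejected(self):
        t = np.linspace(0, 1, 8)[:, None]
        pts = t * np.array([1e5, 2e5, -1e4])
        with pytest.raises(FitError, match="collinear"):
            fit_affine(ControlPointTable.from_arrays(pts, pts))


class TestApplyTransform:
    def test_identity(self, rng):
        s = random_tree(rng, n_nodes=10)
        out = apply_transform(AffineTransform.identity(), s)
        np.testing.assert_allclose(out.positions, s.positions)

    def test_pure_translation(self, rng):
        t = AffineTransform(translation=np.array([100.0, -50, 7]))
        pts = rng.uniform(0, 1e4, (5, 3))
        np.testing.assert_allclose(apply_transform(t, pts),
                                   pts + [100, -50, 7])

    def test_matches_matrix_multiply_oracle(self, rng):
        t = random_affine(rng)
        pts = rng.uniform(0, 1e5, (50, 3))
        oracle = pts @ (quat_to_matrix(t.quaternion)
                        @ np.diag(t.scale)).T + t.translation
        np.testing.assert_allclose(apply_transform(t, pts), oracle,
                                   rtol=1e-12)

    def test_inverse_round_trip(self, rng):
        t = random_affine(rng)
        pts = rng.uniform(0, 1e5, (20, 3))
        np.testing.assert_allclose(t.apply_inverse(t.apply(pts)), pts,
                                   rtol=1e-9, atol=1e-6)

    def test_affine_commutes_with_rigid_conjugation(self, rng):
        """Rigidly re-expressing the target frame (and translating the
        source frame) conjugates the fit.  The source-frame rotation must be
        trivial because the anisotropic scale axes are tied to the source
        frame."""
        lm = rng.uniform(0, 1e5, (15, 3))
        truth = random_affine(rng)
        em = truth.apply(lm)
        g_em = AffineTransform(rotation_about_axis([0, 0, 1], 0.7),
                               np.ones(3), np.array([1e4, 2e4, -3e4]))
        shift_lm = np.array([-2e4, 5e3, 7e3])
        fit_conj = fit_affine(ControlPointTable.from_arrays(
            lm + shift_lm, g_em.apply(em)))
        probe = rng.uniform(0, 1e5, (7, 3))
        np.testing.assert_allclose(fit_conj.apply(probe + shift_lm),
                                   g_em.apply(truth.apply(probe)),
                                   rtol=1e-6, atol=1e-2)


class TestLocalOffsetCorrection:
    def test_coincident_anchor_is_noop(self, rng):
        t = random_affine(rng)
        a_lm = rng.uniform(0, 1e5, 3)
        t2 = local_offset_correction(t, a_lm, t.apply(a_lm))
        np.testing.assert_allclose(t2.translation, t.translation, atol=1e-9)

    def test_anchor_residual_zero_and_uniform_shift(self, rng):
        t = random_affine(rng)
        a_lm = rng.uniform(0, 1e5, 3)
        a_em = t.apply(a_lm) + np.array([1000.0, 2000, 3000])
        t2 = local_offset_correction(t, a_lm, a_em)
        np.testing.assert_allclose(t2.apply(a_lm), a_em, atol=1e-9)
        # every other point shifts by exactly the anchor offset
        pts = rng.uniform(0, 1e5, (10, 3))
        np.testing.assert_allclose(t2.apply(pts) - t.apply(pts),
                                   np.tile([1000.0, 2000, 3000], (10, 1)),
                                   atol=1e-9)
        np.testing.assert_allclose(t2.scale, t.scale)
        np.testing.assert_allclose(t2.quaternion, t.quaternion)


class TestResidualError:
    def test_zero_for_exact_transform(self, rng):
        t = random_affine(rng)
        lm = rng.uniform(0, 1e5, (10, 3))
        rep = residual_error(t, ControlPointTable.from_arrays(lm,
                                                              t.apply(lm)))
        assert rep.mean_nm == pytest.approx(0.0, abs=1e-6)

    def test_known_translation_error(self, rng):
        lm = rng.uniform(0, 1e5, (10, 3))
        e = np.array([300.0, 400, 0])  # norm 500
        rep = residual_error(AffineTransform.identity(),
                             ControlPointTable.from_arrays(lm, lm + e))
        np.testing.assert_allclose(rep.residuals_nm, 500.0)
        assert rep.median_nm == pytest.approx(500.0)

    def test_matches_norm_oracle(self, rng):
        t = random_affine(rng)
        lm = rng.uniform(0, 1e5, (12, 3))
        em = rng.uniform(0, 1e5, (12, 3))
        rep = residual_error(t, ControlPointTable.from_arrays(lm, em))
        oracle = np.linalg.norm(em - t.apply(lm), axis=1)
        np.testing.assert_allclose(rep.residuals_nm, oracle)
        assert rep.n == 12


class TestFitFreeform:
    def test_affine_data_keeps_coefficients_small(self, rng):
        truth = random_affine(rng)
        lm = rng.uniform(0, 6e4, (120, 3))
        em = truth.apply(lm)
        cps = ControlPointTable.from_arrays(lm[:100], em[:100])
        hold = ControlPointTable.from_arrays(lm[100:], em[100:])
        aff = fit_affine(cps)
        ff = fit_freeform(cps, aff, initial_spacing=32_000, refinements=2)
        # displacements stay at numerical-noise scale
        for lev in ff.levels:
            assert np.abs(lev.coeffs).max() < 50.0
        r_aff = residual_error(aff, hold).mean_nm
        r_ff = residual_error(ff, hold).mean_nm
        assert r_ff <= max(r_aff * 1.01, 1.0)

    def test_training_residual_non_increasing_across_levels(self, rng):
        lm = rng.uniform(0, 8e4, (150, 3))
        em = lm + 1500 * np.sin(2 * np.pi * lm / 60_000) \
            + rng.normal(0, 100, lm.shape)
        cps = ControlPointTable.from_arrays(lm, em)
        aff = fit_affine(cps)
        prev = residual_error(aff, cps).mean_nm
        for k in range(4):
            ff = fit_freeform(cps, aff, initial_spacing=32_000, refinements=k)
            cur = residual_error(ff, cps).mean_nm
            assert cur <= prev + 1e-6
            prev = cur

    def test_parameter_validation(self, rng):
        lm = rng.uniform(0, 1e4, (10, 3))
        cps = ControlPointTable.from_arrays(lm, lm)
        with pytest.raises(ValueError):
            fit_freeform(cps, initial_spacing=-1)
        with pytest.raises(ValueError):
            fit_freeform(cps, refinements=-2)

    def test_serialization_round_trip(self, rng):
        lm = rng.uniform(0, 5e4, (60, 3))
        em = lm + 800 * np.sin(2 * np.pi * lm / 40_000)
        cps = ControlPointTable.from_arrays(lm, em)
        ff = fit_freeform(cps, refinements=1)
        back = transform_from_dict(ff.to_dict())
        probe = rng.uniform(0, 5e4, (10, 3))
        np.testing.assert_allclose(back.apply(probe), ff.apply(probe),
                                   rtol=1e-12)


class TestBootstrapCurve:
    def _noiseless_affine_cps(self, rng, n=80):
        truth = random_affine(rng)
        lm = rng.uniform(0, 1e5, (n, 3))
        return ControlPointTable.from_arrays(lm, truth.apply(lm))

    def test_noiseless_scene_gives_zero_residuals(self, rng):
        cps = self._noiseless_affine_cps(rng)
        curve = bootstrap_cp_curve(cps, counts=[20], n_reps=3, n_holdout=10,
                                   seed=7)
        assert curve.mean_residual_nm[0] == pytest.approx(0.0, abs=1e-3)

    def test_monotone_trend_with_noise(self, rng):
        truth = random_affine(rng)
        lm = rng.uniform(0, 1e5, (160, 3))
        em = truth.apply(lm) + rng.normal(0, 500, (160, 3))
        cps = ControlPointTable.from_arrays(lm, em)
        curve = bootstrap_cp_curve(cps, counts=[5, 25, 100], n_reps=10,
                                   n_holdout=30, seed=3)
        # residual at many constraints clearly below residual at few
        assert curve.mean_residual_nm[2] < curve.mean_residual_nm[0]

    def test_reproducible_from_seed(self, rng):
        cps = self._noiseless_affine_cps(rng, n=60)
        a = bootstrap_cp_curve(cps, counts=[10, 20], n_reps=4, n_holdout=10,
                               seed=11)
        b = bootstrap_cp_curve(cps, counts=[10, 20], n_reps=4, n_holdout=10,
                               seed=11)
        np.testing.assert_array_equal(a.mean_residual_nm, b.mean_residual_nm)

    def test_insufficient_cps_rejected(self, rng):
        cps = self._noiseless_affine_cps(rng, n=20)
        with pytest.raises(ValueError):
            bootstrap_cp_curve(cps, counts=[15], n_holdout=30)
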