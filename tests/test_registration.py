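"""Transform algebra, resampling oracles, registration recovery, QC."""

import numpy as np
import pytest

from tractgex.core_volumes import AffineTransform, Volume, volume_from_spacing
from tractgex.registration import (
    RegistrationConfig,
    TransformChain,
    affine_register,
    compose,
    histogram_qc,
    load_transform,
    resample,
    save_transform,
    select_most_typical,
    upsample_energy,
    warp_magnitude,
)
from tractgex.synthetic_data import PhantomSpec, make_misaligned_pair, make_template

from conftest import smooth_linear_volume


def translation(tx, ty, tz):
    p = AffineTransform.identity_params()
    p[:3] = (tx, ty, tz)
    return AffineTransform.from_params(p)


class TestCompose:
    def test_transform_then_inverse_is_identity(self):
        t = AffineTransform.from_params(
            [1, -2, 0.5, 15, -4, 8, 1.05, 0.95, 1.0, 0.01, 0, 0], center=(2, 2, 2))
        np.testing.assert_allclose(compose([t, t.inverse()]).matrix, np.eye(4), atol=1e-10)

    def test_translations_add(self):
        c = compose([translation(1, 0, 0), translation(0, 2, 0)])
        np.testing.assert_allclose(c.matrix[:3, 3], [1, 2, 0], atol=1e-12)

    def test_associativity(self, rng):
        ts = [AffineTransform.from_params(
            np.concatenate([rng.normal(0, 1, 3), rng.normal(0, 5, 3),
                            1 + rng.normal(0, 0.05, 3), rng.normal(0, 0.01, 3)]))
            for _ in range(3)]
        a = compose([ts[0], ts[1], ts[2]])
        b = compose([compose([ts[0], ts[1]]), ts[2]])
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-10)

    def test_chain_space_labels_must_match(self):
        t = translation(1, 0, 0)
        chain = TransformChain([(t, "a", "b")])
        with pytest.raises(ValueError, match="space mismatch"):
            chain.append(t, "c", "d")
        chain.append(t, "b", "c")
        assert chain.source_space == "a" and chain.target_space == "c"

    def test_composed_equals_sequential_application(self):
        """One-pass resampling through a composed chain matches applying the
        links one by one (trilinear-exact ramp, interior voxels)."""
        vol = smooth_linear_volume()
        ts = [translation(0.3, -0.2, 0.1),
              AffineTransform.from_params([0, 0, 0, 3, 0, 0, 1, 1, 1, 0, 0, 0],
                                          center=vol.world_center()),
              translation(-0.1, 0.15, 0.05)]
        seq = vol
        for t in ts:
            seq = resample(seq, t, vol)
        onepass = resample(vol, compose(ts), vol)
        core = (slice(4, -4),) * 3
        assert np.max(np.abs(seq.data[core] - onepass.data[core])) < 1e-4

    def test_json_round_trip(self, tmp_path):
        t = AffineTransform.from_params([1, 2, 3, 4, 5, 6, 1.1, 0.9, 1.0, 0.01, 0.02, 0.03])
        save_transform(t, tmp_path / "t.json", "diffusion", "template")
        back, src, tgt = load_transform(tmp_path / "t.json")
        np.testing.assert_allclose(back.matrix, t.matrix, atol=1e-12)
        np.testing.assert_allclose(back.params, t.params)
        assert (src, tgt) == ("diffusion", "template")


class TestResample:
    def test_identity_same_grid_exact(self, random_volume):
        out = resample(random_volume, AffineTransform.identity(), random_volume)
        np.testing.assert_allclose(out.data, random_volume.data, atol=1e-12)

    def test_constant_volume_stays_constant_in_interior(self):
        vol = volume_from_spacing(np.full((12, 12, 12), 4.5), 0.5)
        t = AffineTransform.from_params([0.2, -0.1, 0.3, 5, -3, 2, 1, 1, 1, 0, 0, 0],
                                        center=vol.world_center())
        out = resample(vol, t, vol)
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(out.data[core], 4.5, atol=1e-9)

    def test_integer_translation_is_array_shift(self, random_volume):
        dv = random_volume.spacing[0]
        out = resample(random_volume, translation(dv, 0, 0), random_volume)
        np.testing.assert_allclose(out.data[1:], random_volume.data[:-1], atol=1e-6)

    def test_nearest_mode_preserves_values(self, rng):
        vol = volume_from_spacing(rng.integers(0, 5, (10, 10, 10)).astype(float), 0.5)
        out = resample(vol, translation(0.5, 0, 0), vol, mode="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(vol.data))

    def test_missing_value_never_blended(self, rng):
        data = rng.uniform(5.0, 6.0, (12, 12, 12))
        data[4:8, 4:8, 4:8] = -1.0
        vol = volume_from_spacing(data, 0.2, missing_value=-1.0)
        out = resample(vol, translation(0.1, 0.07, 0.0), vol)
        vals = out.data[out.data != -1.0]
        # blending the -1 sentinel into real values would undershoot 5.0
        assert vals.min() > 4.9

    def test_round_trip_through_inverse_close(self, small_phantom):
        tpl = make_template(small_phantom)
        t = AffineTransform.from_params([0.4, -0.3, 0.2, 6, -4, 3, 1.02, 0.98, 1.0, 0, 0, 0],
                                        center=tpl.world_center())
        there = resample(tpl, t, tpl)
        back = resample(there, t.inverse(), tpl)
        core = (slice(6, -6),) * 3
        rng_ = np.ptp(tpl.data)
        mae = np.mean(np.abs(back.data[core] - tpl.data[core]))
        assert mae < 0.05 * rng_

    def test_singular_transform_rejected(self, random_volume):
        with pytest.raises(ValueError):
            AffineTransform(np.diag([1.0, 1.0, 0.0, 1.0]))


class TestUpsampleEnergy:
    def test_factor_8_grid_arithmetic(self, rng):
        vol = volume_from_spacing(rng.random((10, 20, 30)), 0.2, missing_value=-1.0)
        up = upsample_energy(vol)
        assert up.shape == (80, 160, 240)
        np.testing.assert_allclose(up.spacing, [0.025] * 3, rtol=1e-9)

    def test_constant_region_stays_constant(self):
        data = np.full((8, 8, 8), 2.5)
        up = upsample_energy(volume_from_spacing(data, 0.2, missing_value=-1.0))
        core = (slice(8, -8),) * 3
        np.testing.assert_allclose(up.data[core], 2.5, atol=1e-9)

    def test_in_brain_sum_scales_by_512(self, rng):
        from scipy.ndimage import gaussian_filter
        data = gaussian_filter(rng.random((16, 16, 16)), 2.0) + 1.0
        vol = volume_from_spacing(data, 0.2)
        up = upsample_energy(vol)
        core_lo = data[2:-2, 2:-2, 2:-2].sum()
        core_hi = up.data[16:-16, 16:-16, 16:-16].sum()
        assert core_hi == pytest.approx(512 * core_lo, rel=0.02)

    def test_missing_propagates_not_interpolated(self):
        data = np.full((6, 6, 6), 3.0)
        data[:, :, :3] = -1.0
        up = upsample_energy(volume_from_spacing(data, 0.2, missing_value=-1.0))
        assert np.all(np.isin(np.unique(up.data), [-1.0, 3.0]))


class TestHistogramQC:
    def _vol(self, rng, shape=(16, 16, 16)):
        from scipy.ndimage import gaussian_filter
        return volume_from_spacing(gaussian_filter(rng.lognormal(0, 0.4, shape), 1.5), 0.25)

    def test_identity_scores_zero(self, rng):
        v = self._vol(rng)
        assert histogram_qc(v, v).score == 0.0

    def test_voxel_permutation_scores_zero(self, rng):
        v = self._vol(rng)
        permuted = Volume(rng.permutation(v.data.ravel()).reshape(v.shape),
                          v.affine_vox2world)
        assert histogram_qc(v, permuted).score == pytest.approx(0.0, abs=1e-12)

    def test_global_shift_scores_positive(self, rng):
        v = self._vol(rng)
        shifted = Volume(v.data + 1.0, v.affine_vox2world)
        qc = histogram_qc(v, shifted)
        assert qc.score > 0.1 and qc.flagged

    def test_all_missing_rejected(self):
        v = volume_from_spacing(np.full((4, 4, 4), -1.0), 0.2, missing_value=-1.0)
        with pytest.raises(ValueError, match="non-missing"):
            histogram_qc(v, v)


@pytest.fixture(scope="module")
def reg_template():
    spec = PhantomSpec(grid_shape=(32, 32, 32), spacing=0.25, rng_seed=3)
    return spec, make_template(spec)


def _recovery_errors(t_est, t_true, vol):
    d = t_est.matrix @ np.linalg.inv(t_true.matrix)
    c = vol.world_center()
    trans = np.linalg.norm((d[:3, :3] @ c + d[:3, 3]) - c)
    U, _, Vt = np.linalg.svd(d[:3, :3])
    ang = np.degrees(np.arccos(np.clip((np.trace(U @ Vt) - 1) / 2, -1, 1)))
    return trans, ang


class TestAffineRegister:
    CFG = RegistrationConfig(metric="ncc", rot_search_deg=0.0, coarse_search=False)

    def test_self_registration_is_identity(self, reg_template):
        spec, tpl = reg_template
        t = affine_register(tpl, tpl, self.CFG)
        trans, ang = _recovery_errors(t, AffineTransform.identity(), tpl)
        assert trans < 0.1 * spec.spacing and ang < 0.5

    def test_planted_translation_recovered(self, reg_template):
        spec, tpl = reg_template
        p = AffineTransform.identity_params()
        p[:3] = np.array([2.0, 3.0, -1.0]) * spec.spacing
        moving, t_true = make_misaligned_pair(tpl, (0, 0, 0), seed=0, params=p,
                                              pad_frac=0.25)
        t_est = affine_register(moving, tpl, self.CFG)
        trans, _ = _recovery_errors(t_est, t_true, tpl)
        assert trans < 0.2 * spec.spacing

    def test_planted_rotation_and_scale_recovered(self, reg_template):
        spec, tpl = reg_template
        p = AffineTransform.identity_params()
        p[5] = 10.0           # 10 deg about axis 2
        p[6:9] = 1.1          # isotropic scale
        moving, t_true = make_misaligned_pair(tpl, (0, 0, 0), seed=0, params=p,
                                              pad_frac=0.25)
        cfg = RegistrationConfig(metric="ncc", rot_search_deg=15, rot_search_step_deg=15)
        t_est = affine_register(moving, tpl, cfg)
        _, ang = _recovery_errors(t_est, t_true, tpl)
        assert ang < 1.0
        assert np.allclose(t_est.params[6:9], 1.1, atol=0.02)

    def test_nmi_metric_also_recovers(self, reg_template):
        """Cross-modality metric: register against a nonlinear remap of the
        template intensities (same geometry, different contrast)."""
        spec, tpl = reg_template
        p = AffineTransform.identity_params()
        p[:3] = (0.5, -0.25, 0.25)
        moving, t_true = make_misaligned_pair(tpl, (0, 0, 0), seed=0, params=p,
                                              pad_frac=0.25)
        remapped = Volume(np.sqrt(tpl.data + 0.1), tpl.affine_vox2world)
        cfg = RegistrationConfig(metric="nmi", rot_search_deg=0, coarse_search=False)
        t_est = affine_register(moving, remapped, cfg)
        trans, ang = _recovery_errors(t_est, t_true, tpl)
        assert trans < 0.5 * spec.spacing and ang < 1.5

    def test_constant_image_rejected(self, reg_template):
        _, tpl = reg_template
        flat = Volume(np.zeros(tpl.shape), tpl.affine_vox2world)
        with pytest.raises(ValueError, match="constant"):
            affine_register(flat, tpl)

    def test_simpleitk_oracle_agrees(self, reg_template):
        """Independent registration oracle: SimpleITK recovers the same
        planted translation our implementation does."""
        sitk = pytest.importorskip("SimpleITK")
        spec, tpl = reg_template
        p = AffineTransform.identity_params()
        p[:3] = (0.5, -0.5, 0.25)
        moving, t_true = make_misaligned_pair(tpl, (0, 0, 0), seed=0, params=p,
                                              pad_frac=0.25)
        t_ours = affine_register(moving, tpl, self.CFG)

        def to_sitk(vol):
            img = sitk.GetImageFromArray(np.asarray(vol.data, np.float64).transpose(2, 1, 0))
            img.SetSpacing(tuple(float(s) for s in vol.spacing))
            img.SetOrigin(tuple(float(o) for o in vol.affine_vox2world[:3, 3]))
            return img

        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsCorrelation()
        reg.SetOptimizerAsRegularStepGradientDescent(1.0, 1e-4, 200)
        reg.SetInterpolator(sitk.sitkLinear)
        tx = sitk.TranslationTransform(3)
        reg.SetInitialTransform(tx, inPlace=True)
        reg.Execute(to_sitk(tpl), to_sitk(moving))
        # sitk maps fixed->moving points; our transform maps moving->fixed
        sitk_trans = -np.asarray(tx.GetParameters())
        np.testing.assert_allclose(sitk_trans, t_ours.params[:3], atol=0.1 * spec.spacing)

    def test_warp_magnitude_of_identity_is_zero(self, reg_template):
        _, tpl = reg_template
        assert warp_magnitude(AffineTransform.identity(), tpl) == 0.0


class TestSelectMostTypical:
    def test_identical_volumes_tie_break_to_first(self, reg_template):
        _, tpl = reg_template
        idx, W = select_most_typical([tpl, tpl.copy(), tpl.copy()])
        assert idx == 0
        assert W.shape == (3, 3)
        np.testing.assert_allclose(np.diag(W), 0.0, atol=1e-12)
        assert np.all(W < 0.05)

    def test_undistorted_volume_is_picked(self, reg_template):
        spec, tpl = reg_template
        jittered = [make_misaligned_pair(tpl, (0.4, 3.0, 0.0), seed=s)[0]
                    for s in (1, 2)]
        idx, W = select_most_typical([jittered[0], tpl, jittered[1]])
        assert idx == 1

    def test_needs_at_least_two(self, reg_template):
        _, tpl = reg_template
        with pytest.raises(ValueError):
            select_most_typical([tpl])
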