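import numpy as np
import pytest

from tbmpipe import phantom
from tbmpipe.core_image import DisplacementField, Volume, voxel_to_world_grid
from tbmpipe.phantom import RadialBlobTransform
from tbmpipe.registration import (AffineTransform, BSplineTransform,
                                  CompositeTransform, groupwise_register,
                                  jacobian_log_det, mean_positional_distance,
                                  ncc, register_linear, register_nonrigid,
                                  sample_at_world)


def _iso_volume(data, spacing=0.15):
    shape = np.asarray(data.shape, float)
    aff = np.eye(4)
    aff[:3, :3] = np.diag([spacing] * 3)
    aff[:3, 3] = -(shape - 1) / 2 * spacing
    return Volume(data, aff)


@pytest.fixture(scope="module")
def clean_spec():
    return phantom.PhantomSpec(seed=5, noise_sd={"invivo": 2.0,
                                                 "exvivo": 2.0},
                               subject_variability_sd=0.0)


@pytest.fixture(scope="module")
def template48(clean_spec):
    return phantom.build_template(clean_spec)


@pytest.fixture(scope="module")
def sphere_pair():
    """Layered spherical phantom and its 25% contracted version (analytic).

    Internal shells give the registration interior gradient information, so
    the imposed volume change is recoverable throughout the region, not only
    at the outer boundary.
    """
    shape = (48, 48, 48)
    aff = np.eye(4)
    aff[:3, :3] = np.diag([0.15] * 3)
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2 * 0.15

    radius = 2.6  # mm

    def intensity(points):
        r = np.linalg.norm(points, axis=-1)
        core = 100.0 / (1.0 + np.exp((r - radius) / 0.12))
        mid = -45.0 / (1.0 + np.exp((r - radius * 0.7) / 0.12))
        inner = 60.0 / (1.0 + np.exp((r - radius * 0.4) / 0.12))
        return core + mid + inner

    pts = voxel_to_world_grid(shape, aff)
    fixed = Volume(intensity(pts), aff)
    blob = RadialBlobTransform((0, 0, 0), (radius,) * 3, 0.25,
                               transition_mm=0.4)
    moving = Volume(intensity(blob.backward(pts)), aff)
    r = np.linalg.norm(pts, axis=-1)
    mask = r <= radius
    # the same anatomical sphere, as it appears in the contracted image
    mask_contracted = r <= radius * 0.75 ** (1.0 / 3.0)
    return fixed, moving, mask, mask_contracted


class TestAffineJacobian:
    def test_exact_logdet_for_random_affine(self, rng, template48):
        tpl, _ = template48
        m = np.eye(4)
        m[:3, :3] = np.eye(3) + rng.normal(0, 0.1, (3, 3))
        t = AffineTransform(m)
        jm = jacobian_log_det(t, tpl)
        expected = np.log(abs(np.linalg.det(m[:3, :3])))
        np.testing.assert_allclose(jm.log_jdet, expected, atol=1e-9)

    def test_uniform_shrinkage_scale(self, template48):
        # isotropic scale (0.90)^(1/3): log det J = log 0.90 everywhere
        tpl, _ = template48
        s = 0.90 ** (1 / 3)
        m = np.diag([s, s, s, 1.0])
        jm = jacobian_log_det(AffineTransform(m), tpl)
        np.testing.assert_allclose(jm.log_jdet, np.log(0.90), atol=1e-3)

    def test_rigid_validation(self):
        bad = np.eye(4)
        bad[0, 0] = 2.0
        with pytest.raises(ValueError):
            AffineTransform(bad, "rigid")


class TestBSpline:
    def test_identity_transform_zero_jacobian(self, template48):
        tpl, _ = template48
        b = BSplineTransform.identity(tpl.shape, tpl.affine, 4)
        jm = jacobian_log_det(b, tpl, source="nonrigid_only")
        np.testing.assert_allclose(jm.log_jdet, 0.0, atol=1e-12)

    def test_min_spacing_enforced(self, template48):
        tpl, _ = template48
        with pytest.raises(ValueError):
            BSplineTransform.identity(tpl.shape, tpl.affine, 1)

    def test_finite_difference_matches_analytic(self, rng, template48):
        tpl, _ = template48
        b = BSplineTransform.identity(tpl.shape, tpl.affine, 4)
        b.coefs = rng.normal(0, 0.02, b.coefs.shape)
        analytic = b.displacement_gradient_vox()
        fd = np.stack(np.gradient(b.displacement(), axis=(0, 1, 2)), axis=-1)
        inner = (slice(2, -2),) * 3
        assert np.abs(analytic[inner] - fd[inner]).max() < 1e-3

    def test_composite_jacobian_is_sum_of_parts(self, rng, template48):
        # det(M (I + dU)) = det M * det(I + dU): log maps add exactly
        tpl, _ = template48
        m = np.eye(4)
        m[:3, :3] = np.eye(3) * 0.95 + rng.normal(0, 0.02, (3, 3))
        aff = AffineTransform(m)
        b = BSplineTransform.identity(tpl.shape, tpl.affine, 4)
        b.coefs = rng.normal(0, 0.02, b.coefs.shape)
        comp = CompositeTransform(aff, b)
        full = jacobian_log_det(comp, tpl, source="composite")
        nr = jacobian_log_det(comp, tpl, source="nonrigid_only")
        np.testing.assert_allclose(full.log_jdet - nr.log_jdet,
                                   aff.log_det(), atol=1e-9)

    def test_folding_detected(self, template48):
        tpl, _ = template48
        b = BSplineTransform.identity(tpl.shape, tpl.affine, 4)
        b.coefs[...] = 0.0
        b.coefs[4:8, 4:8, 4:8, :] = 5.0  # way beyond invertibility
        with pytest.raises(ValueError, match="non-invertible"):
            jacobian_log_det(b, tpl, source="nonrigid_only")


class TestLinearRegistration:
    def test_self_registration_identity(self, template48):
        tpl, _ = template48
        t = register_linear(tpl, tpl, dof_class="rigid")
        shift_vox = np.abs(t.matrix[:3, 3]) / tpl.spacing
        assert shift_vox.max() < 0.05
        angle = np.degrees(np.arccos(
            np.clip((np.trace(t.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert angle < 0.1

    def test_known_shift_recovered(self, template48):
        tpl, _ = template48
        moving = Volume(np.roll(tpl.data, 3, axis=0), tpl.affine)
        t = register_linear(moving, tpl, dof_class="rigid")
        np.testing.assert_allclose(t.matrix[:3, 3] / tpl.spacing,
                                   [3.0, 0.0, 0.0], atol=0.1)

    def test_known_scale_recovered(self, template48):
        tpl, _ = template48
        s = 0.90
        inv = np.diag([1 / s, 1 / s, 1 / s, 1.0])
        pts = voxel_to_world_grid(tpl.shape, tpl.affine)
        moving = Volume(sample_at_world(tpl, pts @ inv[:3, :3].T), tpl.affine)
        t = register_linear(moving, tpl, dof_class="affine")
        np.testing.assert_allclose(np.diag(t.matrix[:3, :3]), [s, s, s],
                                   atol=0.01)

    def test_constant_image_rejected(self, template48):
        tpl, _ = template48
        flat = Volume(np.zeros(tpl.shape), tpl.affine)
        with pytest.raises(ValueError, match="constant"):
            register_linear(flat, tpl)

    def test_ncc_never_regresses_from_init(self, template48):
        tpl, _ = template48
        moving = Volume(np.roll(tpl.data, 2, axis=1), tpl.affine)
        init = register_linear(moving, tpl, dof_class="affine")
        pts = voxel_to_world_grid(tpl.shape, tpl.affine)

        def score(t):
            return ncc(tpl.data, sample_at_world(moving, t.apply(pts)))

        refined = register_linear(moving, tpl, dof_class="affine", init=init,
                                  maxiter=1)
        assert score(refined) >= score(init) - 1e-9


class TestNonrigidRegistration:
    def test_self_registration_near_zero(self, template48):
        tpl, _ = template48
        res = register_nonrigid(tpl, tpl, n_steps=15)
        disp = np.linalg.norm(res.transform.displacement(), axis=-1)
        p99 = np.percentile(disp, 99)
        assert p99 < 0.1 * float(np.mean(tpl.spacing))

    def test_similarity_trace_monotone(self, sphere_pair):
        fixed, moving, _, _ = sphere_pair
        res = register_nonrigid(moving, fixed, n_steps=25)
        trace = np.asarray(res.similarity_trace)
        assert np.all(np.diff(trace) >= -1e-3)

    def test_sphere_contraction_recovered(self, sphere_pair):
        fixed, moving, mask, _ = sphere_pair
        res = register_nonrigid(moving, fixed, n_steps=60)
        jm = jacobian_log_det(res.transform, fixed, source="nonrigid_only",
                              mask=mask)
        mean_det = float(np.exp(np.nanmean(jm.log_jdet[mask])))
        assert mean_det == pytest.approx(0.75, abs=0.05)

    def test_approximate_inverse_consistency(self, sphere_pair):
        # each direction is evaluated over the sphere as it appears in its
        # own fixed image; the two region-mean determinants must multiply to
        # ~1
        fixed, moving, mask, mask_contracted = sphere_pair
        fwd = register_nonrigid(moving, fixed, n_steps=150)
        bwd = register_nonrigid(fixed, moving, n_steps=150)
        j_f = jacobian_log_det(fwd.transform, fixed, source="nonrigid_only",
                               mask=mask)
        j_b = jacobian_log_det(bwd.transform, moving, source="nonrigid_only",
                               mask=mask_contracted)
        prod = np.exp(np.nanmean(j_f.log_jdet[mask])) * \
            np.exp(np.nanmean(j_b.log_jdet[mask_contracted]))
        assert prod == pytest.approx(1.0, abs=0.1)

    def test_constant_image_rejected(self, template48):
        tpl, _ = template48
        flat = Volume(np.zeros(tpl.shape), tpl.affine)
        with pytest.raises(ValueError, match="constant"):
            register_nonrigid(flat, tpl)


class TestGroupwise:
    def test_identical_images_give_identity(self, clean_spec):
        spec = phantom.PhantomSpec(grid_shape=(36, 36, 36), seed=2,
                                   noise_sd={"invivo": 0.0, "exvivo": 0.0},
                                   subject_variability_sd=0.0)
        tpl, _ = phantom.build_template(spec)
        images = [tpl.copy() for _ in range(4)]
        gw = groupwise_register(images, n_affine=1, n_nrr=1, seed=0,
                                nrr_steps_per_iteration=4,
                                linear_levels=(4, 2), linear_maxiter=2)
        for t in gw.transforms:
            field = t.displacement_field(gw.average_image)
            # identity within 0.1 voxel at the 99th percentile (tiny NMI
            # histogram-sharpening drift is tolerated at isolated voxels)
            assert np.percentile(field.magnitude(), 99) < 0.1 * 0.15
        scale = np.ptp(tpl.data)
        assert np.abs(gw.average_image.data - tpl.data).mean() < 0.01 * scale
        assert len(gw.iteration_log) == 2

    def test_seed_determinism(self):
        spec = phantom.PhantomSpec(grid_shape=(36, 36, 36), seed=9,
                                   noise_sd={"invivo": 4.0, "exvivo": 4.0})
        images = [phantom.synthesize_subject(spec, "WT", "invivo", i)[0]
                  for i in range(3)]
        kwargs = dict(n_affine=0, n_nrr=1, nrr_steps_per_iteration=4,
                      linear_levels=(4, 2), linear_maxiter=2,
                      linear_sample_step=2)
        a = groupwise_register(images, seed=42, **kwargs)
        b = groupwise_register(images, seed=42, **kwargs)
        assert a.target_index == b.target_index
        np.testing.assert_array_equal(a.average_image.data,
                                      b.average_image.data)

    def test_too_few_images(self, template48):
        tpl, _ = template48
        with pytest.raises(ValueError, match="at least 3"):
            groupwise_register([tpl, tpl])

    def test_stage_error_identifies_stage(self, template48):
        tpl, _ = template48
        flat = Volume(np.zeros(tpl.shape), tpl.affine)
        with pytest.raises(RuntimeError, match="stage 'rigid'"):
            groupwise_register([tpl, flat, tpl], n_affine=0, n_nrr=0, seed=0)

    def test_composite_fields_track_ground_truth(self):
        # phantom subjects with larger random warps: relative transforms
        # between subject pairs must agree with the imposed fields to < 1
        # voxel inside the brain (pairwise differences cancel the arbitrary
        # average-morphology offset)
        spec = phantom.PhantomSpec(seed=13,
                                   noise_sd={"invivo": 3.0, "exvivo": 3.0},
                                   subject_variability_sd=0.08)
        subjects = [phantom.synthesize_subject(spec, "WT", "invivo", i)
                    for i in range(4)]
        images = [s[0] for s in subjects]
        gw = groupwise_register(images, n_affine=1, n_nrr=3, seed=1,
                                nrr_steps_per_iteration=12,
                                linear_levels=(4, 2), linear_maxiter=3,
                                linear_sample_step=2)
        avg = gw.average_image
        brain = avg.data > 30
        spacing = float(np.mean(avg.spacing))
        mapped = [t.apply_on_reference(avg) for t in gw.transforms]
        sampled = [sample_field(s[2].vectors, s[0], m)
                   for s, m in zip(subjects, mapped)]
        errs, baselines = [], []
        for i in range(len(subjects)):
            for j in range(i + 1, len(subjects)):
                rel = (mapped[i] - mapped[j]) + (sampled[i] - sampled[j])
                errs.append(
                    float(np.linalg.norm(rel, axis=-1)[brain].mean()))
                baselines.append(float(np.linalg.norm(
                    sampled[i] - sampled[j], axis=-1)[brain].mean()))
        assert float(np.mean(errs)) < spacing
        # registration must actually explain the imposed variability
        assert float(np.mean(errs)) < float(np.mean(baselines))


def sample_field(u, vol, points):
    """Sample each component of a subject-grid field at world points."""
    comps = [sample_at_world(Volume(u[..., c], vol.affine), points)
             for c in range(3)]
    return np.stack(comps, axis=-1)


class TestMPD:
    def _field(self, vec, shape=(6, 6, 6), parts=("nonrigid",)):
        v = np.zeros((*shape, 3))
        v[...] = vec
        return DisplacementField(v, np.eye(4), frozenset(parts))

    def test_zero_fields(self):
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        mpd = mean_positional_distance(
            [self._field((0, 0, 0), parts=()) for _ in range(3)], ref)
        np.testing.assert_array_equal(mpd.data, 0.0)

    def test_hand_computed_two_fields(self):
        # |(1,2,2)| = 3, |(0,0,0)| = 0 -> MPD = 1.5 mm
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        mpd = mean_positional_distance(
            [self._field((1.0, 2.0, 2.0)), self._field((0, 0, 0), parts=())],
            ref)
        np.testing.assert_allclose(mpd.data, 1.5, atol=1e-12)
        assert mpd.n == 2

    def test_order_invariance(self, rng):
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        fields = [self._field(rng.normal(size=3)) for _ in range(4)]
        a = mean_positional_distance(fields, ref)
        b = mean_positional_distance(fields[::-1], ref)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_global_parts_rejected(self):
        ref = Volume(np.zeros((6, 6, 6)), np.eye(4))
        bad = self._field((1, 0, 0), parts=("global", "nonrigid"))
        with pytest.raises(ValueError, match="global"):
            mean_positional_distance([bad], ref)

    def test_geometry_mismatch_rejected(self):
        ref = Volume(np.zeros((8, 8, 8)), np.eye(4))
        with pytest.raises(ValueError, match="geometry"):
            mean_positional_distance([self._field((1, 0, 0))], ref)
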