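import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tbmpipe.registration.maps import JacobianMap
from tbmpipe.tbm_stats import (StatConfig, bh_threshold, effect_size_maps,
                               fdr_correct, n_arm_from_stdev, pooled_stdev,
                               sample_size_map, smooth_map, voxelwise_ttest)


def _jmap(data, spacing=0.15):
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return JacobianMap(np.asarray(data, float), aff, "composite")


def _jmaps_from_stack(stack, spacing=0.15):
    return [_jmap(s, spacing) for s in stack]


class TestStatConfig:
    def test_defaults_give_printed_z_values(self):
        cfg = StatConfig()
        assert cfg.z_alpha_half == 1.96
        assert cfg.z_one_minus_beta == 0.84

    def test_validation(self):
        with pytest.raises(ValueError):
            StatConfig(q=1.5)
        with pytest.raises(ValueError):
            StatConfig(fwhm_mm=-1)


class TestSmoothing:
    def test_impulse_fwhm_in_voxels(self):
        # 0.2 mm FWHM on a 0.04 mm grid -> 5-voxel FWHM response
        data = np.zeros((41, 41, 41))
        data[20, 20, 20] = 1.0
        out = smooth_map(_jmap(data, spacing=0.04), fwhm_mm=0.2)
        profile = out.log_jdet[:, 20, 20]
        half = profile.max() / 2
        above = np.nonzero(profile >= half)[0]
        lo = np.interp(half, [profile[above[0] - 1], profile[above[0]]],
                       [above[0] - 1, above[0]])
        hi = np.interp(half, [profile[above[-1] + 1], profile[above[-1]]],
                       [above[-1] + 1, above[-1]])
        assert hi - lo == pytest.approx(5.0, abs=0.2)

    def test_constant_invariance(self):
        data = np.full((20, 20, 20), 0.37)
        mask = np.zeros((20, 20, 20), bool)
        mask[5:15, 5:15, 5:15] = True
        out = smooth_map(_jmap(data), fwhm_mm=0.5, mask=mask)
        np.testing.assert_allclose(out.log_jdet[mask], 0.37, atol=1e-9)

    def test_gaussian_semigroup(self, rng):
        data = rng.normal(size=(32, 32, 32))
        f = 0.45
        twice = smooth_map(smooth_map(_jmap(data), f), f)
        once = smooth_map(_jmap(data), f * np.sqrt(2.0))
        inner = (slice(6, -6),) * 3
        rmsd = np.sqrt(np.mean(
            (twice.log_jdet[inner] - once.log_jdet[inner])**2))
        assert rmsd < 1e-3

    def test_small_fwhm_warns_and_noops(self):
        data = np.ones((8, 8, 8))
        with pytest.warns(UserWarning, match="half a voxel"):
            out = smooth_map(_jmap(data, spacing=0.15), fwhm_mm=0.05)
        np.testing.assert_array_equal(out.log_jdet, data)


class TestTTest:
    def test_identical_groups(self, rng):
        maps = _jmaps_from_stack(rng.normal(size=(3, 6, 6, 6)))
        stat = voxelwise_ttest(maps, [m for m in maps],
                               np.ones((6, 6, 6), bool))
        np.testing.assert_allclose(stat.t_map, 0.0, atol=1e-12)
        np.testing.assert_allclose(stat.p_map, 1.0, atol=1e-12)

    def test_hand_computed_case(self):
        # A = {.1,.2,.3}, B = {.4,.5,.6}: textbook pooled-variance t
        a = np.array([0.1, 0.2, 0.3])
        b = np.array([0.4, 0.5, 0.6])
        shape = (1, 1, 1)
        stat = voxelwise_ttest(
            _jmaps_from_stack(a.reshape(3, 1, 1, 1)),
            _jmaps_from_stack(b.reshape(3, 1, 1, 1)),
            np.ones(shape, bool))
        sp = np.sqrt(((2) * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4)
        t_hand = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert stat.t_map[0, 0, 0] == pytest.approx(t_hand, abs=1e-12)
        assert stat.df == 4

    def test_matches_scipy_on_random_maps(self, rng):
        a = rng.normal(size=(4, 10, 10, 10))
        b = rng.normal(0.2, 1.1, size=(5, 10, 10, 10))
        stat = voxelwise_ttest(_jmaps_from_stack(a), _jmaps_from_stack(b),
                               np.ones((10, 10, 10), bool))
        # independent oracle: scipy's two-sample t, voxel by voxel
        t_ref, p_ref = sps.ttest_ind(a.reshape(4, -1), b.reshape(5, -1),
                                     axis=0)
        np.testing.assert_allclose(stat.t_map.ravel(), t_ref, atol=1e-10)
        np.testing.assert_allclose(stat.p_map.ravel(), p_ref, atol=1e-10)

    def test_type_one_error_rate(self, rng):
        fractions = []
        for _ in range(20):
            a = rng.normal(size=(5, 10, 10, 10))
            b = rng.normal(size=(5, 10, 10, 10))
            stat = voxelwise_ttest(_jmaps_from_stack(a),
                                   _jmaps_from_stack(b),
                                   np.ones((10, 10, 10), bool))
            fractions.append(float((stat.p_map < 0.05).mean()))
        assert 0.03 <= np.mean(fractions) <= 0.07

    def test_zero_variance_flagged(self):
        a = np.zeros((2, 2, 2, 2))
        b = np.zeros((2, 2, 2, 2))
        stat = voxelwise_ttest(_jmaps_from_stack(a), _jmaps_from_stack(b),
                               np.ones((2, 2, 2), bool))
        assert stat.degenerate.all()
        np.testing.assert_allclose(stat.p_map, 1.0)
        np.testing.assert_allclose(stat.t_map, 0.0)

    def test_too_few_subjects(self, rng):
        maps = _jmaps_from_stack(rng.normal(size=(1, 4, 4, 4)))
        with pytest.raises(ValueError):
            voxelwise_ttest(maps, maps, np.ones((4, 4, 4), bool))


class TestFDR:
    def test_all_small_p_rejected(self):
        p = np.full((10, 10, 1), 0.001)
        t = np.ones_like(p)
        stat = _stat_from(p, t)
        stat = fdr_correct(stat, q=0.05)
        assert stat.fdr_mask.sum() == 100

    def test_step_up_hand_case(self):
        # p = {.01, .02, .04, .9}: k* = 2, since .04 > 3 * .05 / 4 = .0375
        # but .02 <= 2 * .05 / 4 (enumerating the step-up rule by hand)
        p = np.array([0.01, 0.02, 0.04, 0.9]).reshape(4, 1, 1)
        stat = _stat_from(p, np.ones_like(p))
        stat = fdr_correct(stat, q=0.05)
        assert stat.fdr_mask.ravel().tolist() == [True, True, False, False]

    def test_step_up_hand_case_three_rejections(self):
        # p = {.01, .02, .03, .9}: .03 <= 3 * .05 / 4 -> first three rejected
        p = np.array([0.01, 0.02, 0.03, 0.9]).reshape(4, 1, 1)
        stat = _stat_from(p, np.ones_like(p))
        stat = fdr_correct(stat, q=0.05)
        assert stat.fdr_mask.ravel().tolist() == [True, True, True, False]

    def test_never_exceeds_uncorrected(self, rng):
        p = rng.uniform(size=(20, 20, 1))
        stat = _stat_from(p, np.ones_like(p))
        stat = fdr_correct(stat, q=0.05)
        assert stat.fdr_mask.sum() <= (p < 0.05).sum()

    def test_matches_statsmodels(self, rng):
        # dual route: our step-up vs statsmodels' BH on the same family
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=400) ** 2
        crit = bh_threshold(p, 0.05)
        reject_ref, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(p <= crit, reject_ref)

    def test_fdr_control_simulation(self, rng):
        # 50 replicates of a uniform null with a planted-signal-free family:
        # mean false-discovery proportion stays near/below q
        fdps = []
        for _ in range(50):
            p = rng.uniform(size=500)
            crit = bh_threshold(p, 0.05)
            nrej = int((p <= crit).sum())
            fdps.append(1.0 if nrej > 0 else 0.0)
        mean = float(np.mean(fdps))
        se = float(np.std(fdps, ddof=1) / np.sqrt(len(fdps)))
        assert mean <= 0.05 + 2 * se + 1e-12

    def test_empty_mask_rejected(self):
        p = np.ones((2, 2, 2))
        stat = _stat_from(p.reshape(1, *p.shape), np.zeros((1, *p.shape)))
        with pytest.raises(ValueError):
            fdr_correct(stat, mask=np.zeros((2, 2, 2), bool))

    def test_dependence_variant_is_more_conservative(self, rng):
        p = rng.uniform(size=300) ** 1.5
        assert bh_threshold(p, 0.05, dependence=True) <= \
            bh_threshold(p, 0.05, dependence=False)


def _stat_from(p, t):
    """Wrap raw p/t grids in a StatMaps for fdr tests."""
    from tbmpipe.tbm_stats import StatMaps
    p = np.asarray(p, float)
    shape = p.shape[1:] if p.ndim == 4 else p.shape
    p3 = p.reshape(shape) if p.ndim != 3 else p
    t3 = np.asarray(t, float).reshape(p3.shape)
    return StatMaps(t3, p3, np.eye(4), df=8,
                    mask=np.ones(p3.shape, bool),
                    direction=np.sign(t3))


class TestEffectSize:
    def test_null_effect(self, rng):
        base = rng.normal(size=(3, 4, 4, 4))
        power = effect_size_maps(_jmaps_from_stack(base.copy()),
                                 _jmaps_from_stack(base.copy()))
        np.testing.assert_allclose(power.cohens_d, 0.0, atol=1e-12)

    def test_hand_computed_case(self):
        # UT = {0.70, 0.80}, WT = {1.00, 1.10}
        ut = np.array([0.70, 0.80]).reshape(2, 1, 1, 1)
        wt = np.array([1.00, 1.10]).reshape(2, 1, 1, 1)
        power = effect_size_maps(_jmaps_from_stack(ut),
                                 _jmaps_from_stack(wt))
        assert power.pooled_stdev[0, 0, 0] == pytest.approx(
            np.sqrt((0.005 + 0.005) / 2), abs=1e-6)
        assert power.cohens_d[0, 0, 0] == pytest.approx(-4.243, abs=1e-3)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=(4, 5, 5, 5))
        b = rng.normal(0.3, 1.0, size=(4, 5, 5, 5))
        d1 = effect_size_maps(_jmaps_from_stack(a),
                              _jmaps_from_stack(b)).cohens_d
        d2 = effect_size_maps(_jmaps_from_stack(b),
                              _jmaps_from_stack(a)).cohens_d
        np.testing.assert_allclose(d1, -d2, atol=1e-10)

    def test_pooled_stdev_formula(self, rng):
        a = rng.normal(size=(5, 50))
        b = rng.normal(size=(7, 50))
        sp = pooled_stdev(a, b)
        expected = np.sqrt((4 * a.var(0, ddof=1) + 6 * b.var(0, ddof=1))
                           / 10)
        np.testing.assert_allclose(sp, expected, atol=1e-12)


class TestSampleSize:
    def test_hand_case_sd_quarter(self):
        # sd equal to the 25% effect: ceil(2 * 2.8^2) = 16
        assert n_arm_from_stdev(0.25) == 16

    def test_hand_case_sd_tenth(self):
        # ceil(2 * 7.84 * 0.01 / 0.0625) = ceil(2.5088) = 3
        assert n_arm_from_stdev(0.10) == 3

    def test_zero_sd_floors_at_two(self):
        assert n_arm_from_stdev(0.0) == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            StatConfig(effect_fraction=0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.0, 2.0), st.floats(0.0, 2.0))
    def test_monotone_in_stdev(self, s1, s2):
        lo, hi = sorted((s1, s2))
        assert n_arm_from_stdev(lo) <= n_arm_from_stdev(hi)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.05, 0.9), st.floats(0.05, 0.9))
    def test_antitone_in_effect(self, e1, e2):
        lo, hi = sorted((e1, e2))
        n_lo = n_arm_from_stdev(0.2, StatConfig(effect_fraction=lo))
        n_hi = n_arm_from_stdev(0.2, StatConfig(effect_fraction=hi))
        assert n_lo >= n_hi

    def test_map_version(self, rng):
        wt = rng.normal(0, 0.1, size=(6, 8, 8, 8))
        power = sample_size_map(_jmaps_from_stack(wt))
        assert power.n_arm.min() >= 2
        sd = wt.std(0, ddof=1)
        expected = np.maximum(
            np.ceil(2 * (1.96 + 0.84) ** 2 * sd**2 / 0.0625), 2)
        np.testing.assert_array_equal(power.n_arm, expected.astype(int))
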