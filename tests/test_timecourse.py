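"""Unit tests for registration, density normalization and statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eaekit as ek
from eaekit.datatypes import ValidationError


class TestRegistration:
    def test_identical_frames_zero_shift(self):
        rng = np.random.default_rng(0)
        frame = rng.random((64, 64))
        reg = ek.register(np.stack([frame, frame, frame]))
        assert reg.shifts == [(0, 0), (0, 0), (0, 0)]

    def test_recovers_injected_drift_exactly(self):
        stack, drifts = ek.simulate_drifting_stack(
            n_frames=5, drifts=[(0, 0), (3, -2), (-4, 1), (0, 5), (-5, -5)],
            seed=1)
        reg = ek.register(stack, max_shift=8)
        assert reg.shifts == drifts

    def test_registration_undoes_shift(self):
        stack, _ = ek.simulate_drifting_stack(
            n_frames=2, drifts=[(0, 0), (4, -3)], seed=2)
        reg = ek.register(stack, max_shift=6)
        ref, moved = stack[0], reg.frames[1]
        # compare on the interior unaffected by zero padding
        assert np.allclose(ref[8:-8, 8:-8], moved[8:-8, 8:-8])

    def test_noisy_frames_within_one_pixel(self):
        stack, drifts = ek.simulate_drifting_stack(
            n_frames=6, max_drift=4, noise_sd=0.2, seed=3)  # SNR ~ 5
        reg = ek.register(stack, max_shift=8)
        for got, true in zip(reg.shifts, drifts):
            assert abs(got[0] - true[0]) <= 1 and abs(got[1] - true[1]) <= 1

    def test_blank_frame_raises(self):
        stack = np.stack([np.random.default_rng(0).random((32, 32)),
                          np.zeros((32, 32))])
        with pytest.raises(ValidationError):
            ek.register(stack)

    def test_estimator_wrapper(self):
        stack, drifts = ek.simulate_drifting_stack(
            n_frames=3, drifts=[(0, 0), (2, 2), (-1, 0)], seed=4)
        reg = ek.StackRegistrar(max_shift=5).fit(stack)
        assert reg.shifts_ == drifts
        assert reg.get_params()["max_shift"] == 5


def tc_frame(rows):
    return pd.DataFrame(rows)


class TestNormalizeDensities:
    def test_constant_course_all_ones(self):
        rows = [{"mouse": "m0", "day": d, "EGFP": 5.0, "EYFP": 2.0, "double": 1.0}
                for d in (0, 10, 11, 13, 14)]
        out = ek.normalize_densities(tc_frame(rows))
        assert np.allclose(out[["EGFP", "EYFP", "double"]], 1.0)

    def test_two_day_bin_mean(self):
        rows = [
            {"mouse": "m0", "day": 0, "EGFP": 1.0, "EYFP": 1.0, "double": 1.0},
            {"mouse": "m0", "day": 10, "EGFP": 2.0, "EYFP": 1.0, "double": 1.0},
            {"mouse": "m0", "day": 11, "EGFP": 4.0, "EYFP": 1.0, "double": 1.0},
        ]
        out = ek.normalize_densities(tc_frame(rows))
        assert out.loc[out["bin"] == "10-11", "EGFP"].iloc[0] == pytest.approx(3.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        rows = [{"mouse": "m0", "day": d, "EGFP": float(v), "EYFP": 1.0,
                 "double": 1.0}
                for d, v in zip((0, 10, 11, 13, 14), rng.uniform(1, 9, 5))]
        base = ek.normalize_densities(tc_frame(rows))
        scaled_rows = [dict(r, EGFP=r["EGFP"] * 7.5) for r in rows]
        scaled = ek.normalize_densities(tc_frame(scaled_rows))
        assert np.allclose(base["EGFP"], scaled["EGFP"])

    def test_zero_baseline_mouse_excluded(self):
        rows = [
            {"mouse": "m0", "day": 0, "EGFP": 0.0, "EYFP": 1.0, "double": 1.0},
            {"mouse": "m0", "day": 10, "EGFP": 2.0, "EYFP": 1.0, "double": 1.0},
            {"mouse": "m1", "day": 0, "EGFP": 1.0, "EYFP": 1.0, "double": 1.0},
            {"mouse": "m1", "day": 10, "EGFP": 2.0, "EYFP": 1.0, "double": 1.0},
        ]
        out = ek.normalize_densities(tc_frame(rows))
        assert set(out["mouse"]) == {"m1"}

    def test_missing_baseline_raises(self):
        rows = [{"mouse": "m0", "day": 10, "EGFP": 1.0, "EYFP": 1.0,
                 "double": 1.0}]
        with pytest.raises(ValidationError):
            ek.normalize_densities(tc_frame(rows))


def mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = np.concatenate([x, y])
    n = len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return ((xs[:, None] > ys[None, :]).sum()
                + 0.5 * (xs[:, None] == ys[None, :]).sum())

    u_obs = u_of(range(n))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n)]
    mid = len(x) * len(y) / 2
    return np.mean([abs(u - mid) >= abs(u_obs - mid) - 1e-12 for u in us])


class TestMannWhitney:
    def test_extreme_small_sample(self):
        u, p = ek.mann_whitney([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples(self):
        _, p = ek.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p > 0.99

    def test_u_identity(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=5), rng.normal(size=7)
        ux, _ = ek.mann_whitney(x, y)
        uy, _ = ek.mann_whitney(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("nx,ny,seed", [(3, 4, 0), (4, 4, 1), (2, 5, 2),
                                            (3, 5, 3)])
    def test_matches_enumeration_oracle(self, nx, ny, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=nx)
        y = rng.normal(0.8, size=ny)
        _, p = ek.mann_whitney(x, y)
        assert p == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            ek.mann_whitney([], [1.0])


class TestKruskalWallis:
    def test_identical_constant_groups(self):
        h, p = ek.kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert h == 0.0

    def test_two_groups_consistent_with_mw_normal_approx(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=30)
        _, p_kw = ek.kruskal_wallis([x, y])
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert p_kw == pytest.approx(res.pvalue, rel=1e-6)

    def test_single_group_raises(self):
        with pytest.raises(ValidationError):
            ek.kruskal_wallis([[1.0, 2.0]])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            g = rng.normal(size=(3, 10))
            _, p = ek.kruskal_wallis(list(g))
            rejections += p < 0.05
        rate = rejections / reps
        assert 0.035 < rate < 0.065


class TestAnova:
    def test_equal_group_means_f_zero(self):
        f, p = ek.anova_oneway([[1.0, 2.0, 3.0], [0.0, 2.0, 4.0]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(0.7, size=9)
        f, p_f = ek.anova_oneway([x, y])
        t, p_t = stats.ttest_ind(x, y)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_zero_variance_equal_means_raises(self):
        with pytest.raises(ValidationError):
            ek.anova_oneway([[1.0, 1.0], [1.0, 1.0]])

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(10)
        reps = 4000
        rej = sum(ek.anova_oneway(list(rng.normal(size=(3, 10))))[1] < 0.05
                  for _ in range(reps))
        assert 0.035 < rej / reps < 0.065


class TestSpearman:
    def test_perfect_antimonotone(self):
        rho, p = ek.spearman_permutation([1, 2, 3, 4, 5], [10, 8, 6, 4, 2],
                                         n_perm=2000, seed=0)
        assert rho == pytest.approx(-1.0)
        assert p < 0.05

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 10, 20)
        y = rng.uniform(1, 10, 20)
        rho1, _ = ek.spearman_permutation(x, y, n_perm=500, seed=1)
        rho2, _ = ek.spearman_permutation(np.log(x), y**3, n_perm=500, seed=1)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_independent_pairs_small_rho(self):
        rng = np.random.default_rng(12)
        rho, p = ek.spearman_permutation(rng.normal(size=60),
                                         rng.normal(size=60),
                                         n_perm=2000, seed=2)
        assert abs(rho) < 0.3
        assert p > 0.01

    def test_constant_input_raises(self):
        with pytest.raises(ValidationError):
            ek.spearman_permutation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_score_axon_correlation_on_generated_data(self):
        tc = ek.simulate_timecourse(n_mice=9, seed=13)
        rho, p = ek.score_axon_correlation(tc[tc["day"] >= 8], n_perm=2000,
                                           seed=3)
        assert rho < 0
        assert p < 0.05


class TestDepthPartition:
    def test_all_surface_cells_meningeal(self):
        men, par = ek.depth_partition([0.0, 0.0, 0.0], d_meningeal=30.0)
        assert (men, par) == (3, 0)

    def test_counts_sum(self):
        rng = np.random.default_rng(14)
        depths = rng.uniform(0, 100, 57)
        men, par = ek.depth_partition(depths)
        assert men + par == 57

    def test_negative_depth_raises(self):
        with pytest.raises(ValidationError):
            ek.depth_partition([-1.0, 5.0])

    def test_meningeal_fraction_decreases_with_infiltration(self):
        """The generated top-down gradient flattens as cells infiltrate."""
        early = ek.simulate_cell_depths(600, day=10, seed=15)
        late = ek.simulate_cell_depths(600, day=15, seed=16)
        fe = ek.depth_partition(early)[0] / 600
        fl = ek.depth_partition(late)[0] / 600
        assert fe > fl


def test_holm_correction_monotone_and_bounded():
    p = [0.01, 0.04, 0.03, 0.2]
    adj = ek.holm_correction(p)
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    # smallest raw p scaled by the full family size
    assert adj[0] == pytest.approx(0.04)
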