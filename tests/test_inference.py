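import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from infantfmri.inference import (
    PermutationResult,
    cluster_fp_threshold,
    cluster_size_null,
    fdr_correct,
    interaction_summary,
    one_sample_perm,
    threshold_and_cluster,
    two_sample_perm,
    twoway_anova_perm,
)


def _one_sample_t(x):
    return x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))


def _two_sample_t(a, b):
    na, nb = len(a), len(b)
    sp2 = (a.var(ddof=1) * (na - 1) + b.var(ddof=1) * (nb - 1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestOneSamplePerm:
    def test_exhaustive_matches_brute_force(self):
        """n=8 with all 256 sign patterns: p equals explicit enumeration."""
        rng = np.random.default_rng(0)
        V = rng.normal(0.3, 1.0, (8, 6))
        res = one_sample_perm(V, n_perm=256, seed=0)
        assert res.exhaustive
        for v in range(6):
            x = V[:, v]
            obs = abs(_one_sample_t(x))
            count = 0
            for signs in itertools.product((1, -1), repeat=8):
                count += abs(_one_sample_t(np.array(signs) * x)) >= obs - 1e-12
            assert res.p_uncorrected[v] == pytest.approx(count / 256)

    def test_all_zero_values_flagged_p_one(self):
        res = one_sample_perm(np.zeros((5, 3)), n_perm=100, seed=0)
        assert np.all(res.p_uncorrected == 1.0)
        assert np.all(res.zero_variance)

    def test_null_p_values_uniform(self):
        """Fraction of p <= alpha on null data within the binomial 95% CI."""
        rng = np.random.default_rng(12)
        V = rng.standard_normal((12, 1000))
        res = one_sample_perm(V, n_perm=500, seed=1)
        for alpha in (0.05, 0.01):
            frac = (res.p_uncorrected <= alpha).sum()
            lo, hi = stats.binom.interval(0.95, 1000, alpha)
            assert lo <= frac <= hi

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(3)
        V = rng.standard_normal((10, 50))
        a = one_sample_perm(V, n_perm=200, seed=5)
        b = one_sample_perm(V, n_perm=200, seed=5)
        np.testing.assert_array_equal(a.p_uncorrected, b.p_uncorrected)

    def test_shift_increases_statistic_where_signs_agree(self):
        rng = np.random.default_rng(4)
        V = rng.normal(0.5, 1.0, (15, 40))
        base = one_sample_perm(V, n_perm=10, seed=0)
        shifted = one_sample_perm(V + 0.5, n_perm=10, seed=0)
        pos = base.t_obs > 0
        assert np.all(np.abs(shifted.t_obs[pos]) >= np.abs(base.t_obs[pos]))

    def test_p_floor_respected(self):
        rng = np.random.default_rng(5)
        V = rng.normal(5.0, 0.1, (25, 4))  # overwhelming effect
        res = one_sample_perm(V, n_perm=99, seed=0)
        assert np.all(res.p_uncorrected >= 1 / 100)


class TestTwoSamplePerm:
    def test_exhaustive_matches_brute_force(self):
        """3+3 subjects: p equals enumeration over the 20 relabelings."""
        rng = np.random.default_rng(1)
        A = rng.normal(1.0, 1.0, (3, 4))
        B = rng.normal(0.0, 1.0, (3, 4))
        res = two_sample_perm(A, B, n_perm=20, seed=0)
        assert res.exhaustive and res.n_perm == 20
        pooled = np.vstack([A, B])
        for v in range(4):
            x = pooled[:, v]
            obs = abs(_two_sample_t(A[:, v], B[:, v]))
            count = 0
            for combo in itertools.combinations(range(6), 3):
                sel = np.zeros(6, bool)
                sel[list(combo)] = True
                count += abs(_two_sample_t(x[sel], x[~sel])) >= obs - 1e-12
            assert res.p_uncorrected[v] == pytest.approx(count / 20)

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((4, 5))
        res = two_sample_perm(A, A.copy(), n_perm=50, seed=0)
        assert np.all(res.p_uncorrected > 0.95)

    def test_pooled_null_statistics_label_invariant(self):
        """Permuting group labels leaves the pooled null t distribution alone."""
        rng = np.random.default_rng(6)
        X = rng.standard_normal((12, 30))
        r1 = two_sample_perm(X[:6], X[6:], n_perm=400, seed=7, return_null=True)
        perm = rng.permutation(12)
        Y = X[perm]
        r2 = two_sample_perm(Y[:6], Y[6:], n_perm=400, seed=7, return_null=True)
        ks = stats.ks_2samp(r1.t_null.ravel(), r2.t_null.ravel())
        assert ks.pvalue > 0.01

    def test_group_recovery_enriches_true_rois(self, roi_small):
        """With a planted group difference in frontal-limbic ROIs, those voxels
        are enriched among p < 0.005."""
        rng = np.random.default_rng(8)
        shape = roi_small.shape
        signal = np.isin(roi_small, [2, 3, 4, 5, 6]).astype(float)
        A = 0.6 * signal[None] + rng.normal(0, 0.26, (29, *shape))
        B = -0.4 * signal[None] + rng.normal(0, 0.26, (29, *shape))
        res = two_sample_perm(A, B, n_perm=2000, seed=9)
        p = res.p_volume()
        sig = signal.astype(bool)
        hit_in = (p[sig] < 0.005).mean()
        hit_out = (p[~sig] < 0.005).mean()
        odds_in = hit_in / (1 - hit_in)
        odds_out = max(hit_out, 1e-6) / (1 - max(hit_out, 1e-6))
        assert odds_in / odds_out > 1


class TestThresholdAndCluster:
    def _result_from_p(self, p_vol, t_vol=None):
        p = p_vol.ravel()
        t = (t_vol if t_vol is not None else 10.0 * (p_vol <= 0.005)).ravel()
        return PermutationResult(
            t_obs=t, p_uncorrected=p, n_perm=1000, seed=0,
            null_mean=np.zeros_like(p), null_sd=np.ones_like(p),
            zero_variance=np.zeros_like(p, dtype=bool), shape=p_vol.shape,
        )

    def test_min_size_filter_keeps_three_and_up(self):
        """Components of sizes 1..10: with min_size 3 the smallest survivor is 3."""
        p = np.ones((80, 12, 12))
        x0 = 0
        for size in range(1, 11):
            p[x0:x0 + size, 0, 0] = 0.001  # disjoint line segments along x
            x0 += size + 2
        table, labels = threshold_and_cluster(self._result_from_p(p), alpha=0.005, min_size=3)
        assert table["size_voxels"].min() == 3
        assert len(table) == 8  # sizes 3..10 survive
        assert table["size_voxels"].is_monotonic_decreasing

    def test_no_suprathreshold_voxels_gives_empty_table(self):
        table, labels = threshold_and_cluster(self._result_from_p(np.ones((6, 6, 6))))
        assert table.empty
        assert not labels.any()

    def test_connectivity_semantics_for_diagonal_touch(self):
        p = np.ones((6, 6, 6))
        p[1, 1, 1] = p[2, 2, 1] = 0.001  # touch only across an in-plane diagonal
        res = self._result_from_p(p)
        t26, _ = threshold_and_cluster(res, min_size=1, connectivity=26)
        t6, _ = threshold_and_cluster(res, min_size=1, connectivity=6)
        assert len(t26) == 1
        assert len(t6) == 2

    def test_roi_membership_annotated(self, roi_small):
        p = np.ones(roi_small.shape)
        p[roi_small == 2] = 0.001
        table, _ = threshold_and_cluster(self._result_from_p(p), roi_masks=roi_small)
        assert table.loc[0, "member_roi_labels"] == (2,)


class TestFdrCorrect:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.03]), [0.03])

    def test_hand_computed_by_example(self):
        """BY step-up with c(4) = 1 + 1/2 + 1/3 + 1/4 = 25/12."""
        p = np.array([0.001, 0.01, 0.02, 0.8])
        c4 = 25 / 12
        raw = p * 4 * c4 / np.array([1, 2, 3, 4])
        expected = np.minimum.accumulate(np.minimum(raw, 1.0)[::-1])[::-1]
        np.testing.assert_allclose(fdr_correct(p), expected, rtol=1e-12)

    def test_all_ones_stay_one_and_q_dominates_p(self):
        np.testing.assert_array_equal(fdr_correct([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1.0, 50)
        q = fdr_correct(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_empty_and_invalid_inputs(self):
        assert fdr_correct([]).size == 0
        with pytest.raises(ValueError):
            fdr_correct([0.0, 0.5])


class TestClusterFpThreshold:
    def test_ubiquitous_size_two_clusters_force_threshold_three(self):
        null = [[2]] * 50
        assert cluster_fp_threshold(null, expected_fp=1.0, min_size=1) == 3

    def test_no_constraint_returns_min_size(self):
        null = [[5, 4], [3]]
        assert cluster_fp_threshold(null, expected_fp=np.inf, min_size=3) == 3

    def test_unattainable_expectation_warns(self):
        null = [[4, 4, 4]] * 10
        with pytest.warns(UserWarning):
            out = cluster_fp_threshold(null, expected_fp=0.0, min_size=1)
        assert out == 5

    def test_self_consistent_on_held_out_permutations(self):
        """The threshold calibrated on half the null keeps the empirical
        false-positive cluster rate below target on the other half."""
        rng = np.random.default_rng(3)
        shape = (10, 10, 10)
        V = rng.standard_normal((12, *shape))
        res = one_sample_perm(V, n_perm=200, seed=4, return_null=True)
        sizes = cluster_size_null(res.t_null, shape, alpha=0.05, connectivity=6)
        thr = cluster_fp_threshold(sizes[:100], expected_fp=1.0)
        held = sizes[100:]
        rate = np.mean([sum(1 for s in img if s >= thr) for img in held])
        assert rate < 1.0


class TestTwowayAnovaPerm:
    def test_additive_truth_gives_null_interaction(self):
        a = np.repeat(["x", "y"], 6)
        b = np.tile(np.repeat(["u", "v"], 3), 2)
        y = 1.0 * (a == "x") + 2.0 * (b == "u")  # exactly additive, no noise
        res = twoway_anova_perm(y, a, b, n_perm=100, seed=0)
        assert res["A:B"]["F"] == pytest.approx(0.0, abs=1e-18)
        assert res["A:B"]["p"] == 1.0

    def test_exhaustive_main_effect_matches_enumeration(self):
        """2x2 with 3 per cell: main-effect p equals the within-stratum
        relabeling enumeration computed with statsmodels F values."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(1)
        a = np.repeat(["x", "y"], 6)
        b = np.tile(np.repeat(["u", "v"], 3), 2)
        y = rng.normal(0, 1, 12) + 0.8 * (a == "x")

        def f_a(labels):
            df = pd.DataFrame({"y": y, "A": labels, "B": b})
            tab = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", df).fit(), typ=2)
            return float(tab.loc["C(A)", "F"])

        obs = f_a(a)
        strata = [np.where(b == lev)[0] for lev in ("u", "v")]
        count, total = 0, 0
        for c1 in itertools.combinations(strata[0], int((a[strata[0]] == "x").sum())):
            for c2 in itertools.combinations(strata[1], int((a[strata[1]] == "x").sum())):
                labels = np.full(12, "y")
                labels[list(c1)] = "x"
                labels[list(c2)] = "x"
                count += f_a(labels) >= obs - 1e-12
                total += 1
        res = twoway_anova_perm(y, a, b, exhaustive=True)
        assert res["A"]["p"] == pytest.approx(count / total)

    def test_interaction_type_one_error(self):
        """Null 2x2 (7/cell): interaction rejection rate near nominal 5%."""
        a = np.repeat(["x", "y"], 14)
        b = np.tile(np.repeat(["u", "v"], 7), 2)
        rej = 0
        n_sim = 300
        for s in range(n_sim):
            rng = np.random.default_rng(10_000 + s)
            y = rng.standard_normal(28) + 0.5 * (a == "x") - 0.3 * (b == "u")
            res = twoway_anova_perm(y, a, b, n_perm=199, seed=s)
            rej += res["A:B"]["p"] <= 0.05
        assert 0.02 <= rej / n_sim <= 0.08

    def test_empty_cell_rejected(self):
        a = np.array(["x", "x", "y", "y"])
        b = np.array(["u", "u", "u", "u"])
        with pytest.raises(ValueError):
            twoway_anova_perm(np.zeros(4), a, b)


class TestInteractionSummary:
    def _setup(self, ctl_pos, ctl_neg, pmd_pos, pmd_neg, n=6, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        shape = (6, 6, 6)
        labels = np.zeros(shape, int)
        labels[2:4, 2:4, 2:4] = 1
        table = pd.DataFrame([
            {"cluster_id": 1, "size_voxels": 8, "peak_statistic": 5.0,
             "peak_x": 2, "peak_y": 2, "peak_z": 2, "member_roi_labels": (),
             "p_cluster": 0.001, "q_fdr": np.nan}
        ])
        maps, groups = [], []
        for g, pos, neg in (("control", ctl_pos, ctl_neg), ("PMD", pmd_pos, pmd_neg)):
            for _ in range(n):
                maps.append({
                    "positive": np.full(shape, pos) + rng.normal(0, noise, shape),
                    "negative": np.full(shape, neg) + rng.normal(0, noise, shape),
                })
                groups.append(g)
        return table, labels, maps, np.array(groups)

    def test_recovers_valence_preference_pattern(self):
        table, labels, maps, groups = self._setup(0.9, 0.3, 0.3, 0.7)
        out = interaction_summary(table, labels, maps, groups, n_boot=200, seed=1)
        s = out[0]
        assert s["direction"] == "control>PMD_for_positive"
        assert s["cells"][("control", "positive")]["mean"] > s["cells"][("control", "negative")]["mean"]
        assert s["cells"][("PMD", "negative")]["mean"] >= s["cells"][("PMD", "positive")]["mean"]
        lo, hi = s["cells"][("control", "positive")]["lo"], s["cells"][("control", "positive")]["hi"]
        assert lo <= 0.9 <= hi

    def test_identical_cells_flag_mixed(self):
        table, labels, maps, groups = self._setup(0.5, 0.5, 0.5, 0.5, noise=0.001)
        out = interaction_summary(table, labels, maps, groups, n_boot=50, seed=2)
        assert out[0]["direction"] == "mixed"

    def test_scaling_preserves_flags_and_doubles_means(self):
        table, labels, maps, groups = self._setup(0.9, 0.3, 0.3, 0.7, noise=0.0)
        out1 = interaction_summary(table, labels, maps, groups, n_boot=50, seed=3)
        doubled = [{k: 2 * v for k, v in m.items()} for m in maps]
        out2 = interaction_summary(table, labels, doubled, groups, n_boot=50, seed=3)
        assert out1[0]["direction"] == out2[0]["direction"]
        for key in out1[0]["cells"]:
            assert out2[0]["cells"][key]["mean"] == pytest.approx(
                2 * out1[0]["cells"][key]["mean"])

    def test_empty_cluster_table_rejected(self):
        with pytest.raises(ValueError):
            interaction_summary(pd.DataFrame(), np.zeros((2, 2, 2)), [], [])
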