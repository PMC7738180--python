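"""Overlap tests: cosine against a set-intersection oracle, shuffle-null
calibration against the hypergeometric expectation, bounds, and the
repeated-measures comparison against a sums-of-squares oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codebrain import glm, overlap
from conftest import make_binary_map


class TestCosineSimilarity:
    def test_identical_and_disjoint(self):
        a = make_binary_map([1, 1, 0, 0])
        b = make_binary_map([0, 0, 1, 1])
        assert overlap.cosine_similarity(a, a) == 1.0
        assert overlap.cosine_similarity(a, b) == 0.0

    def test_worked_example(self):
        a = make_binary_map([1, 1, 0, 0])
        b = make_binary_map([1, 0, 1, 0])
        assert overlap.cosine_similarity(a, b) == pytest.approx(0.5)

    def test_zero_map_rejected(self):
        a = make_binary_map([1, 0])
        z = make_binary_map([0, 0])
        with pytest.raises(ValueError, match="all-zero"):
            overlap.cosine_similarity(a, z)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(2, 64), st.integers(0, 2**32 - 1))
    def test_matches_set_intersection_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 2, size=n)
        b = rng.integers(0, 2, size=n)
        if a.sum() == 0 or b.sum() == 0:
            return
        got = overlap.cosine_similarity(make_binary_map(a), make_binary_map(b))
        A = set(np.flatnonzero(a))
        B = set(np.flatnonzero(b))
        assert got == pytest.approx(len(A & B) / np.sqrt(len(A) * len(B)))

    def test_symmetry(self, rng):
        a = make_binary_map(rng.integers(0, 2, 30) | np.eye(1, 30, 0, dtype=int)[0])
        b = make_binary_map(rng.integers(0, 2, 30) | np.eye(1, 30, 5, dtype=int)[0])
        assert overlap.cosine_similarity(a, b) == overlap.cosine_similarity(b, a)


class TestShuffleNull:
    def test_mean_matches_hypergeometric_expectation(self, rng):
        n = 400
        a = np.zeros(n, int)
        a[rng.choice(n, 80, replace=False)] = 1
        b = np.zeros(n, int)
        b[rng.choice(n, 120, replace=False)] = 1
        amap, bmap = make_binary_map(a), make_binary_map(b)
        null = overlap.shuffle_null(amap, bmap, n_shuffle=400, hemisphere=None,
                                    rng=np.random.default_rng(0))
        expect = np.sqrt(80 * 120) / n
        mc_sd = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean() - expect) <= 3 * mc_sd

    def test_fully_active_code_map_constant(self):
        n = 100
        code = make_binary_map(np.ones(n, int))
        loc = make_binary_map((np.arange(n) < 25).astype(int))
        null = overlap.shuffle_null(code, loc, n_shuffle=10, hemisphere=None,
                                    rng=np.random.default_rng(1))
        assert np.allclose(null, np.sqrt(25 / n))

    def test_deterministic_given_seed(self, rng):
        a = make_binary_map((rng.uniform(size=50) < 0.3).astype(int) | (np.arange(50) == 0))
        b = make_binary_map((rng.uniform(size=50) < 0.3).astype(int) | (np.arange(50) == 1))
        n1 = overlap.shuffle_null(a, b, n_shuffle=20, seed=5, hemisphere=None)
        n2 = overlap.shuffle_null(a, b, n_shuffle=20, seed=5, hemisphere=None)
        assert np.array_equal(n1, n2)


class TestGroupBootstrapP:
    def test_observed_above_all_nulls(self, rng):
        nulls = rng.uniform(0.0, 0.2, size=(8, 100))
        p = overlap.group_bootstrap_p(np.full(8, 0.9), nulls, n_boot=10_000, seed=0)
        assert p == 0.0
        p = overlap.group_bootstrap_p(np.full(8, -1.0), nulls, n_boot=10_000, seed=0)
        assert p == 1.0

    def test_self_null_mid_p(self, rng):
        nulls = rng.uniform(0.1, 0.3, size=(10, 200))
        observed = nulls.mean(axis=1)
        p = overlap.group_bootstrap_p(observed, nulls, n_boot=50_000, seed=1)
        assert 0.35 < p < 0.65

    def test_subject_relabeling_invariance(self, rng):
        nulls = rng.uniform(0, 0.4, size=(6, 100))
        observed = rng.uniform(0.1, 0.3, size=6)
        p1 = overlap.group_bootstrap_p(observed, nulls, n_boot=50_000, seed=2)
        perm = rng.permutation(6)
        p2 = overlap.group_bootstrap_p(observed[perm], nulls[perm], n_boot=50_000, seed=2)
        assert abs(p1 - p2) < 0.02

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            overlap.group_bootstrap_p(np.empty(0), np.empty((0, 10)))


class TestSplitHalf:
    def test_ten_unordered_partitions(self):
        parts = overlap.split_half_partitions(6)
        assert len(parts) == 10
        seen = set()
        for first, second in parts:
            assert len(first) == len(second) == 3
            assert set(first) | set(second) == set(range(6))
            key = frozenset([frozenset(first), frozenset(second)])
            assert key not in seen
            seen.add(key)

    def _run_stats(self, beta, var):
        with np.errstate(divide="ignore"):
            t = beta / np.sqrt(var)
        return glm.RunStats(beta=beta, variance=var, t=t, p=np.ones_like(beta), df=50)

    def test_noiseless_data_gives_unit_ceiling(self):
        n = 200
        hemis = np.array(["L"] * (n // 2) + ["R"] * (n // 2))
        truth = np.zeros(n)
        truth[:30] = 6.0
        runs = [self._run_stats(truth.copy(), np.ones(n)) for _ in range(6)]
        bound = overlap.split_half_upper_bound([runs], hemis)
        assert bound == pytest.approx(1.0)

    def test_noisy_data_lowers_ceiling(self, rng):
        n = 400
        hemis = np.array(["L"] * (n // 2) + ["R"] * (n // 2))
        truth = np.zeros(n)
        truth[:60] = 1.5  # weak per-run signal: unreliable half-maps
        strong = np.zeros(n)
        strong[:60] = 8.0
        noisy = [
            [self._run_stats(t + rng.standard_normal(n), np.ones(n)) for _ in range(6)]
            for t in (truth, strong)
        ]
        weak_bound = overlap.split_half_upper_bound([noisy[0]], hemis)
        strong_bound = overlap.split_half_upper_bound([noisy[1]], hemis)
        assert strong_bound > 0.9
        assert weak_bound < strong_bound - 0.2

    def test_wrong_run_count_rejected(self):
        n = 10
        hemis = np.array(["L"] * 5 + ["R"] * 5)
        runs = [self._run_stats(np.ones(n), np.ones(n))] * 4
        with pytest.raises(ValueError, match="6 runs"):
            overlap.split_half_upper_bound([runs], hemis)


def rm_anova_oracle(table):
    """Brute-force repeated-measures ANOVA sums of squares."""
    table = np.asarray(table, float)
    n, k = table.shape
    grand = table.mean()
    ss_task = n * ((table.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((table.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_task - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_task / df1) / (ss_err / df2), (df1, df2)


class TestCompareTasks:
    def test_identical_columns_zero_f(self, rng):
        col = rng.uniform(0, 0.5, size=8)
        out = overlap.compare_tasks(np.column_stack([col] * 4))
        assert out["F"] == 0.0

    def test_df_for_study_shape(self, rng):
        table = rng.uniform(0, 0.6, size=(15, 4))
        out = overlap.compare_tasks(table)
        assert out["df"] == (3, 42)

    def test_matches_sum_of_squares_oracle(self, rng):
        table = rng.uniform(0, 1, size=(3, 3))
        out = overlap.compare_tasks(table)
        F_oracle, df_oracle = rm_anova_oracle(table)
        assert out["F"] == pytest.approx(F_oracle, rel=1e-8)
        assert out["df"] == df_oracle

    def test_posthoc_table(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, size=(10, 4)),
                             columns=["logic", "math", "language", "msit"])
        out = overlap.compare_tasks(table)
        ph = out["posthoc"]
        assert len(ph) == 6  # all unordered pairs
        assert np.all(ph["p_fdr"] >= ph["p"] - 1e-12)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame({"a": [0.1, np.nan], "b": [0.2, 0.3]})
        with pytest.raises(ValueError, match="missing"):
            overlap.compare_tasks(table)


def test_planted_overlap_monotone_recovery():
    """Group-mean estimated overlaps track planted targets 0.1 / 0.3 / 0.5."""
    from codebrain.surface_synth import CONTRASTS, SynthConfig, generate_subject

    means = []
    for target in (0.1, 0.3, 0.5):
        t = np.full((5, 5), 0.05)
        np.fill_diagonal(t, 1.0)
        tm = pd.DataFrame(t, index=CONTRASTS, columns=CONTRASTS)
        tm.loc["code", "logic"] = tm.loc["logic", "code"] = target
        cfg = SynthConfig(n_vertices_per_hemi=1000, overlap_targets=tm,
                          laterality_mu=0.2, laterality_sd=0.1, seed=31)
        vals = []
        for i in range(15):
            ds = generate_subject(cfg, i)
            vals.append(
                overlap.cosine_similarity(
                    ds.contrast_binary("code"), ds.contrast_binary("logic"), hemisphere="L"
                )
            )
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
    for got, want in zip(means, (0.1, 0.3, 0.5)):
        assert abs(got - want) <= 0.05
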