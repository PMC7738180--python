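"""GLM tests: HRF shape, design construction, OLS against a normal-equations
oracle, fixed-effects pooling, and BH-FDR against brute force."""

import numpy as np
import pytest
from scipy import stats

from codebrain import designgen as dg
from codebrain import glm


class TestCanonicalHrf:
    t = np.arange(0, 32.01, 0.05)

    def test_zero_at_onset_and_peak_location(self):
        h = glm.canonical_hrf(self.t)
        assert h[0] == 0.0
        peak_t = self.t[np.argmax(h)]
        assert 4.0 <= peak_t <= 6.0
        assert h.max() == pytest.approx(1.0)

    def test_undershoot(self):
        h = glm.canonical_hrf(self.t)
        assert h.min() < 0
        assert abs(h.min()) < h.max()

    def test_agrees_with_reference_spm_shape(self):
        # independent oracle: nilearn's canonical SPM HRF
        from nilearn.glm.first_level import spm_hrf

        ours = glm.canonical_hrf(np.arange(0, 32, 0.1))
        ref = spm_hrf(t_r=0.1, oversampling=1, time_length=32)
        n = min(ours.size, ref.size)
        r = np.corrcoef(ours[:n], ref[:n])[0, 1]
        assert r > 0.95

    def test_rejects_bad_grid(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(np.array([-1.0, 0.0, 1.0]))


class TestBuildDesign:
    def _mini_schedule(self, onsets, conds, durs=24.0):
        import pandas as pd

        rows = []
        for onset, cond in zip(onsets, conds):
            rows.append(
                {
                    "onset": onset,
                    "duration": durs,
                    "trial_type": cond,
                    "run": 1,
                    "function_id": 0,
                    "phase": "function",
                    "answer": True,
                }
            )
        return dg.TrialSchedule(trials=pd.DataFrame(rows), group="A")

    def test_empty_schedule(self):
        import pandas as pd

        sched = dg.TrialSchedule(trials=pd.DataFrame(columns=dg.EVENT_COLUMNS), group="A")
        X = glm.build_design(sched, tr_s=2.0, n_samples=10)
        assert X.condition_names == []
        assert X.names == ["intercept"]

    def test_single_event_matches_manual_convolution(self):
        sched = self._mini_schedule([0.0], ["for1"])
        tr = 2.0
        X = glm.build_design(sched, tr_s=tr, n_samples=40, include_derivative=False)
        col = X.column("for1")
        dt = 0.01
        fine = np.zeros(int(40 * tr / dt))
        fine[: int(24 / dt)] = 1.0
        hrf = glm.canonical_hrf(np.arange(0, 32, dt))
        manual = np.convolve(fine, hrf)[: fine.size][:: int(tr / dt)]
        r = np.corrcoef(col, manual)[0, 1]
        assert r > 0.999

    def test_six_condition_schedule_column_count(self):
        sched = dg.build_code_schedule("A", 0)
        run1 = sched.trials[sched.trials["run"] == 1].copy()
        run1["onset"] -= run1["onset"].min()
        run1 = dg.TrialSchedule(trials=run1, group="A")
        X = glm.build_design(run1, tr_s=2.0, n_samples=430)
        assert len(X.condition_names) == 6  # for1, for2, if1, if2, fake_for, fake_if
        assert sum(n.endswith("__derivative") for n in X.names) == 6
        assert "intercept" in X.names

    def test_overlapping_events_rejected(self):
        sched = self._mini_schedule([0.0, 10.0], ["for1", "for1"])
        with pytest.raises(ValueError, match="overlap"):
            glm.build_design(sched, tr_s=2.0, n_samples=40)


class TestFitRun:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            X = rng.standard_normal((20, 5))
            Y = rng.standard_normal((20, 3))
            c = rng.standard_normal(5)
            res = glm.fit_run(Y, X, c)
            # oracle: explicit normal equations
            B = np.linalg.solve(X.T @ X, X.T @ Y)
            resid = Y - X @ B
            df = 20 - 5
            s2 = (resid**2).sum(axis=0) / df
            se = np.sqrt(s2 * (c @ np.linalg.solve(X.T @ X, c)))
            t = (c @ B) / se
            assert np.allclose(res.beta, c @ B, atol=1e-8)
            assert np.allclose(res.t, t, atol=1e-8)
            assert np.allclose(res.p, 2 * stats.t.sf(np.abs(t), df), atol=1e-8)

    def test_noiseless_recovery(self, rng):
        X = rng.standard_normal((30, 4))
        beta = rng.standard_normal((4, 2))
        res = glm.fit_run(X @ beta, X, np.array([1, 0, 0, 0]))
        assert np.allclose(res.coefficients, beta, atol=1e-10)

    def test_zero_contrast(self, rng):
        X = rng.standard_normal((15, 3))
        res = glm.fit_run(rng.standard_normal((15, 2)), X, np.zeros(3))
        assert np.all(res.t == 0)
        assert np.all(res.p == 1)

    def test_rank_deficiency_names_columns(self, rng):
        X = rng.standard_normal((10, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError, match="c"):
            glm.fit_run(rng.standard_normal(10), X, np.array([1.0, 0, 0]),
                        names=["a", "b", "c"])

    def test_orthonormal_design_se(self, rng):
        # orthonormal X: (X'X)^-1 = I so se(beta_i) ~ residual sd
        X, _ = np.linalg.qr(rng.standard_normal((200, 4)))
        Y = rng.standard_normal((200, 500))
        res = glm.fit_run(Y, X, np.array([1.0, 0, 0, 0]))
        assert np.mean(res.se) == pytest.approx(1.0, abs=0.05)


class TestFixedEffects:
    hemis = np.array(["L", "R"])

    def _rs(self, beta, var):
        beta, var = np.asarray(beta, float), np.asarray(var, float)
        with np.errstate(divide="ignore"):
            t = beta / np.sqrt(var)
        return glm.RunStats(beta=beta, variance=var, t=t, p=np.ones_like(beta), df=10)

    def test_single_run_identity(self):
        rs = self._rs([1.0, -2.0], [0.5, 2.0])
        zmap, _ = glm.combine_fixed_effects([rs], self.hemis)
        assert np.allclose(zmap.values, rs.beta / np.sqrt(rs.variance))

    def test_two_run_formula(self):
        r1 = self._rs([2.0, 2.0], [1.0, 1.0])
        r2 = self._rs([4.0, 4.0], [1.0, 1.0])
        beta, var = glm.fixed_effects_beta([r1, r2])
        assert np.allclose(beta, 3.0)
        assert np.allclose(var, 0.5)

    def test_equal_variance_is_mean(self, rng):
        runs = [self._rs(rng.standard_normal(2), [1.0, 1.0]) for _ in range(6)]
        beta, _ = glm.fixed_effects_beta(runs)
        assert np.allclose(beta, np.mean([r.beta for r in runs], axis=0))

    def test_permutation_invariance(self, rng):
        runs = [self._rs(rng.standard_normal(2), rng.uniform(0.5, 2, 2)) for _ in range(4)]
        z1, _ = glm.combine_fixed_effects(runs, self.hemis)
        z2, _ = glm.combine_fixed_effects(runs[::-1], self.hemis)
        assert np.allclose(z1.values, z2.values)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            glm.combine_fixed_effects([self._rs([1.0, 1.0], [1.0, 0.0])], self.hemis)


def brute_force_bh(pvals, q):
    """Reject the i largest-ranked p's with sorted p_(i) <= i*q/m, i maximal."""
    p = np.sort(pvals)
    m = p.size
    ks = [i for i in range(1, m + 1) if p[i - 1] <= i * q / m]
    if not ks:
        return np.zeros(m, bool)[np.argsort(np.argsort(pvals))]
    cutoff = p[max(ks) - 1]
    return pvals <= cutoff


class TestFdrBinarize:
    def _pmap(self, p):
        p = np.asarray(p, float)
        hemis = np.array(["L"] * p.size)
        return glm.VertexMap(values=p, kind="p", hemispheres=hemis)

    def test_all_ones_all_zero(self):
        out = glm.fdr_binarize(self._pmap([1.0, 1.0, 1.0]))
        assert out.values.sum() == 0

    def test_worked_example(self):
        out = glm.fdr_binarize(self._pmap([0.005, 0.01, 0.03, 0.04]), q=0.05)
        assert out.values.sum() == 4

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 40))
            p[rng.uniform(size=p.size) < 0.3] /= 100  # some small p's
            got = glm.fdr_binarize(self._pmap(p), q=0.05).values.astype(bool)
            assert np.array_equal(got, brute_force_bh(p, 0.05))

    def test_monotone_in_q(self, rng):
        p = rng.uniform(size=50) ** 2
        low = glm.fdr_binarize(self._pmap(p), q=0.01).values
        high = glm.fdr_binarize(self._pmap(p), q=0.10).values
        assert np.all(high >= low)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            glm.fdr_binarize(self._pmap([]))


def test_fdr_type_i_control_on_null_maps(rng):
    """Under a global null, P(any BH discovery) — the expected false-discovery
    proportion — stays at or below q (+ Monte Carlo slack)."""
    n_maps, n_vertices, n_samples = 200, 40, 60
    X = np.column_stack([rng.standard_normal(n_samples), np.ones(n_samples)])
    hemis = np.array(["L"] * n_vertices)
    hits = 0
    for _ in range(n_maps):
        Y = rng.standard_normal((n_samples, n_vertices))
        res = glm.fit_run(Y, X, np.array([1.0, 0.0]))
        pmap = glm.VertexMap(values=res.p, kind="p", hemispheres=hemis)
        if glm.fdr_binarize(pmap, q=0.05).values.sum() > 0:
            hits += 1
    mc_err = np.sqrt(0.05 * 0.95 / n_maps)
    assert hits / n_maps <= 0.05 + 2 * mc_err
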