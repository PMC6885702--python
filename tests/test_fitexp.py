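"""OPLS-DA model, VIP ranking, cross-validation, and time-course rules."""

import numpy as np
import pandas as pd
import pytest

from mstriad.errors import ValidationError
from mstriad import fitexp as fx
from mstriad import synthetic as syn
from mstriad.quantio import bridge_normalize, split_sets

from conftest import make_design, make_matrix
from _oracles import pls1_scores_eigen


def random_two_class(seed, n=12, k=30):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    y = np.array(["a", "b"] * (n // 2))
    return X, y


class TestFitOplsda:
    def test_discriminative_variable_dominates(self):
        rng = np.random.default_rng(0)
        y = np.array(["a", "b"] * 20)
        code = np.where(y == "b", 1.0, -1.0)
        noise = rng.normal(size=40)
        noise -= code * (noise @ code) / (code @ code)  # pure noise: no class signal
        X = np.column_stack([code, noise])
        m = fx.fit_oplsda(X, y, n_ortho=0)
        assert abs(m.weights_w[0]) > abs(m.weights_w[1])
        assert m.r2y >= 0.99

    def test_predictive_scores_match_eigen_oracle(self):
        """Deflation-based scores agree with an independent eigenvector
        extraction of X'yy'X on small matrices, up to sign."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(6, 3))
            y = np.array(["a", "b"] * 3)
            m = fx.fit_oplsda(X, y, n_ortho=0)
            oracle = pls1_scores_eigen(X, np.where(y == "b", 1.0, -1.0))
            sign = np.sign(oracle @ m.predictive_scores_t)
            np.testing.assert_allclose(
                m.predictive_scores_t, sign * oracle, atol=1e-8
            )

    def test_predictive_scores_match_sklearn_pls(self):
        """With no orthogonal components the predictive scores coincide with
        scikit-learn's NIPALS PLS regression scores, up to sign."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_two_class(20, n=10, k=6)
        code = np.where(y == "b", 1.0, -1.0)
        ref = PLSRegression(n_components=1, scale=True).fit(X, code)
        t_ref = ref.x_scores_[:, 0]
        m = fx.fit_oplsda(X, y, n_ortho=0)
        sign = np.sign(t_ref @ m.predictive_scores_t)
        np.testing.assert_allclose(m.predictive_scores_t, sign * t_ref, atol=1e-8)

    def test_sample_permutation_equivariance(self):
        X, y = random_two_class(1)
        perm = np.random.default_rng(2).permutation(len(y))
        m1 = fx.fit_oplsda(X, y, n_ortho=1)
        m2 = fx.fit_oplsda(X[perm], y[perm], n_ortho=1)
        np.testing.assert_allclose(
            m2.predictive_scores_t, m1.predictive_scores_t[perm], atol=1e-8
        )
        np.testing.assert_allclose(m2.vip, m1.vip, atol=1e-10)

    def test_sign_flip_symmetry(self):
        """Negating the class coding flips scores and weights exactly."""
        X, _ = random_two_class(3)
        y = np.array([0, 1] * 6)
        m1 = fx.fit_oplsda(X, y, n_ortho=1)
        m2 = fx.fit_oplsda(X, 1 - y, n_ortho=1)
        np.testing.assert_allclose(m2.weights_w, -m1.weights_w, atol=1e-10)
        np.testing.assert_allclose(
            m2.predictive_scores_t, -m1.predictive_scores_t, atol=1e-10
        )
        np.testing.assert_allclose(m2.vip, m1.vip, atol=1e-10)

    def test_orthogonal_scores_uncorrelated_with_class(self):
        X, y = random_two_class(4, n=16, k=40)
        m = fx.fit_oplsda(X, y, n_ortho=3)
        code = np.where(y == "b", 1.0, -1.0)
        code = code - code.mean()
        for i in range(3):
            r = np.corrcoef(m.orthogonal_scores_T[:, i], code)[0, 1]
            assert abs(r) < 1e-8

    def test_reconstruction_identity(self):
        X, y = random_two_class(5, n=10, k=20)
        m = fx.fit_oplsda(X, y, n_ortho=2)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        E = (
            Xs
            - np.outer(m.predictive_scores_t, m.predictive_loadings_p)
            - m.orthogonal_scores_T @ m.orthogonal_loadings_P.T
        )
        assert np.abs(E.T @ m.predictive_scores_t).max() < 1e-8
        assert np.abs(E.T @ m.orthogonal_scores_T).max() < 1e-8

    def test_r2x_nondecreasing_in_orthogonal_components(self):
        X, y = random_two_class(6, n=14, k=25)
        r2 = [fx.fit_oplsda(X, y, n_ortho=n).r2x_cum for n in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    def test_unit_norm_weights(self):
        X, y = random_two_class(7)
        m = fx.fit_oplsda(X, y, n_ortho=1)
        assert abs(np.linalg.norm(m.weights_w) - 1.0) < 1e-10

    def test_errors(self):
        X, y = random_two_class(8, n=6, k=4)
        with pytest.raises(ValidationError):
            fx.fit_oplsda(X, np.array(["a"] * 6))  # single class
        with pytest.raises(ValidationError):
            fx.fit_oplsda(X, y, n_ortho=99)  # above rank


class TestVip:
    def test_unit_weight_gives_sqrt_k(self):
        X, y = random_two_class(9, n=8, k=4)
        m = fx.fit_oplsda(X, y, n_ortho=0)
        m.weights_w = np.array([1.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(fx.vip_predictive(m), [2.0, 0.0, 0.0, 0.0])

    def test_mean_square_is_one(self):
        for seed in range(10):
            X, y = random_two_class(seed, n=10, k=17)
            m = fx.fit_oplsda(X, y, n_ortho=1)
            assert abs((m.vip**2).mean() - 1.0) < 1e-10

    def test_ranking_invariant_to_variable_permutation(self):
        X, y = random_two_class(10, n=12, k=20)
        ids = np.array([f"P{i}" for i in range(20)])
        perm = np.random.default_rng(0).permutation(20)
        m1 = fx.fit_oplsda(X, y, n_ortho=1, variable_names=ids)
        m2 = fx.fit_oplsda(X[:, perm], y, n_ortho=1, variable_names=ids[perm])
        rank1 = m1.variable_names[np.argsort(-m1.vip, kind="stable")]
        order2 = {n: v for n, v in zip(m2.variable_names, m2.vip)}
        rank2 = sorted(order2, key=lambda n: -order2[n])
        assert list(rank1) == list(rank2)

    def test_planted_variables_enriched_in_top_vip(self):
        """Variables planted with a 1.5 SD class difference (20 among 1000,
        n=8 per class) dominate the top of the VIP ranking far beyond the
        chance overlap of 0.4; at this sample size sampling noise keeps a
        perfect top-20 out of reach, so the check is on strong median
        enrichment over 50 replicate simulations."""
        overlaps = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            y = np.array(["a"] * 8 + ["b"] * 8)
            X = rng.normal(size=(16, 1000))
            X[y == "b", :20] += 1.5
            m = fx.fit_oplsda(X, y, n_ortho=0)
            top = set(np.argsort(-m.vip)[:20])
            overlaps.append(len(top & set(range(20))))
        assert np.median(overlaps) >= 8
        assert min(overlaps) >= 3

    def test_vip_recall_monotone_in_effect_and_sample_size(self):
        """Recall of planted variables in the top-k grows with effect size
        and with replication (median over 25 seeds per grid cell)."""

        def recall(effect, n_per_class):
            out = []
            for seed in range(25):
                rng = np.random.default_rng(seed)
                y = np.array(["a"] * n_per_class + ["b"] * n_per_class)
                X = rng.normal(size=(2 * n_per_class, 300))
                X[y == "b", :10] += effect
                m = fx.fit_oplsda(X, y, n_ortho=0)
                top = set(np.argsort(-m.vip)[:10])
                out.append(len(top & set(range(10))))
            return np.median(out)

        by_effect = [recall(e, 8) for e in (1.0, 1.5, 2.0)]
        assert all(b >= a for a, b in zip(by_effect, by_effect[1:]))
        by_n = [recall(1.5, n) for n in (3, 4, 8)]
        assert all(b >= a for a, b in zip(by_n, by_n[1:]))


class TestCrossValidation:
    def test_q2_near_one_for_noiseless_predictor(self):
        y = np.array(["a", "b"] * 7)
        X = np.where(y == "b", 1.0, -1.0).reshape(-1, 1)
        assert fx.q2_crossval(X, y, folds=7, n_ortho=0) >= 0.95

    def test_q2_low_under_permutation_null(self):
        ok = 0
        for i in range(50):
            rng = np.random.default_rng(100 + i)
            X = rng.normal(size=(14, 100))
            y = np.array(["a", "b"] * 7)
            rng.shuffle(y)
            ok += fx.q2_crossval(X, y, folds=7, n_ortho=0) < 0.2
        assert ok >= 0.95 * 50

    def test_leave_one_out_runs(self):
        X, y = random_two_class(11, n=8, k=5)
        q2 = fx.q2_crossval(X, y, folds=8, n_ortho=0)
        assert np.isfinite(q2)

    def test_single_class_fold_raises(self):
        # all 'a' samples in fold 0 -> training folds lose a class
        X = np.random.default_rng(0).normal(size=(4, 3))
        y = np.array(["a", "b", "a", "b"])
        with pytest.raises(ValidationError, match="fewer folds"):
            fx.q2_crossval(X, y, folds=2, n_ortho=0)


class TestCvAnova:
    def test_separable_data_highly_significant(self):
        rng = np.random.default_rng(12)
        y = np.array(["a", "b"] * 7)
        X = np.column_stack([np.where(y == "b", 1.0, -1.0), rng.normal(size=14) * 0.01])
        m = fx.fit_oplsda(X, y, n_ortho=0)
        assert fx.cv_anova(X, y, m) < 1e-6

    def test_type_i_error_controlled(self):
        """Independent X and y reject at 5% in at most 10% of runs."""
        rej = 0
        n_runs = 200
        for i in range(n_runs):
            rng = np.random.default_rng(i)
            X = rng.normal(size=(16, 50))
            y = np.array(["a", "b"] * 8)
            m = fx.fit_oplsda(X, y, n_ortho=1)
            rej += fx.cv_anova(X, y, m) < 0.05
        assert rej <= 0.10 * n_runs

    def test_scale_invariance(self):
        X, y = random_two_class(13)
        m = fx.fit_oplsda(X, y, n_ortho=1)
        p1 = fx.cv_anova(X, y, m)
        p2 = fx.cv_anova(X * 1e4, y, fx.fit_oplsda(X * 1e4, y, n_ortho=1))
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestContrastTopk:
    @staticmethod
    def _normalized(seed=0, **kw):
        m, truth = syn.simulate_expression(300, seed=seed, **kw)
        joined, _ = bridge_normalize(split_sets(m))
        return joined, truth

    def test_lists_disjoint_and_bounded(self):
        joined, _ = self._normalized(n_specific=10, n_shared=10)
        res = fx.contrast_topk(joined, "DDW", k=30)
        up = set(res.up["protein_id"])
        down = set(res.down["protein_id"])
        assert not up & down
        assert len(up) <= 30 and len(down) <= 30
        assert (np.diff(res.up["vip"]) <= 1e-12).all()

    def test_recovers_planted_specific_proteins(self):
        joined, truth = self._normalized(n_specific=10, n_shared=10, seed=1)
        res = fx.contrast_topk(joined, "DDW", k=20)
        assert set(truth.specific_up) <= set(res.up["protein_id"])
        assert set(truth.specific_down) <= set(res.down["protein_id"])

    def test_null_contrast_flagged_non_significant(self):
        joined, _ = self._normalized(n_specific=0, n_shared=0, seed=5)
        with pytest.warns(UserWarning, match="not significant"):
            res = fx.contrast_topk(joined, "DDW", k=10)
        assert res.model.q2_cum <= 0

    def test_sign_convention_up_means_higher_in_target(self):
        joined, truth = self._normalized(n_specific=10, n_shared=0, seed=2)
        res = fx.contrast_topk(joined, "DDW", k=5)
        assert list(res.up["protein_id"][:5]) == sorted(
            truth.specific_up, key=lambda p: -res.up.set_index("protein_id")["vip"].get(p, 0)
        )

    def test_k_below_one_rejected(self):
        joined, _ = self._normalized(n_specific=0, n_shared=0)
        with pytest.raises(ValueError):
            fx.contrast_topk(joined, "DDW", k=0)


class TestCharacteristicTime:
    def _timecourse_matrix(self, traj, timepoints=(4.0, 15.0, 26.0, 38.0, 48.0)):
        design = make_design(
            [str(i) for i in range(len(timepoints))],
            ["DDW"] * len(timepoints),
            replicates=[1] * len(timepoints),
            timepoints=list(timepoints),
        )
        return make_matrix(np.atleast_2d(traj), design, ids=["marker"], normalized=True)

    def test_threshold_crossing(self):
        m = self._timecourse_matrix([1.0, 1.0, 1.25, 1.25, 1.25])
        res = fx.characteristic_time(m, ["marker"], [], marker_protein="marker")
        assert res.characteristic_time_h == 26.0
        assert res.reached

    def test_zero_threshold_returns_first_timepoint(self):
        m = self._timecourse_matrix([1.0, 1.0, 1.25, 1.25, 1.25])
        res = fx.characteristic_time(m, ["marker"], [], threshold=0.0,
                                     marker_protein="marker")
        assert res.characteristic_time_h == 4.0

    def test_never_crossing_flags_not_reached(self):
        m = self._timecourse_matrix([1.0, 1.05, 1.1, 1.05, 1.0])
        res = fx.characteristic_time(m, ["marker"], [], marker_protein="marker")
        assert not res.reached
        assert res.characteristic_time_h is None

    def test_missing_marker_raises_by_name(self):
        m = self._timecourse_matrix([1.0] * 5)
        with pytest.raises(KeyError, match="p62"):
            fx.characteristic_time(m, ["marker"], [], marker_protein="p62")

    def test_group_p_rule_fires_at_planted_onset(self):
        hits = 0
        n_runs = 10
        for seed in range(n_runs):
            m, tr = syn.simulate_timecourse(
                120, onset_h=26.0, effect_log2=0.25, noise_sd_log2=0.3,
                n_up=50, n_down=50, seed=seed,
            )
            res = fx.characteristic_time(
                m, tr.specific_up, tr.specific_down, marker_protein=tr.specific_up[0]
            )
            hits += res.group_p_time_h == 26.0
        assert hits >= 8
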