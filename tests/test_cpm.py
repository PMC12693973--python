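"""Edge selection, fold models, leave-one-trial-out CV, permutations,
consensus networks and generalization — checked against naive per-fold
re-implementations and closed-form oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import pearsonr

import dcpm
from dcpm.cpm import (
    CPMResult,
    EdgeSelection,
    _corr_with_pvals,
    consensus_network,
    fit_fold_model,
    generalize,
    loto_cv,
    permutation_test,
    select_edges,
)


# ---------------------------------------------------------------------------
# Naive reference: per-fold loop, scipy correlation, explicit refits
# ---------------------------------------------------------------------------

def naive_loto(X: np.ndarray, y: np.ndarray, construct: str,
               alpha: float = 0.01) -> np.ndarray:
    """Reference leave-one-trial-out dCPM: literal per-fold recomputation.

    Deletes the held-out row, reselects edges with scipy's pearsonr, refits
    the subnetwork-sum model, predicts the held-out trial.
    """
    n = len(y)
    preds = np.full(n, np.nan)
    for k in range(n):
        keep = np.delete(np.arange(n), k)
        Xtr, ytr = X[keep], y[keep]
        pos, neg = set(), set()
        for e in range(X.shape[1]):
            if np.ptp(Xtr[:, e]) == 0:
                continue
            r, p = pearsonr(Xtr[:, e], ytr)
            if p < alpha:
                (pos if r > 0 else neg).add(e)
        if not pos and not neg:
            continue
        sel = EdgeSelection(positive=frozenset(pos), negative=frozenset(neg),
                            alpha=alpha)
        model = fit_fold_model(Xtr, ytr, sel, construct)
        preds[k] = model.predict(X[k:k + 1])[0]
    return preds


@pytest.fixture(scope="module")
def small_problem(coupled_matrix):
    X, truth = coupled_matrix
    return X.values, X.behavior("arousal"), X.behavior("memory")


# ---------------------------------------------------------------------------
# select_edges
# ---------------------------------------------------------------------------

class TestSelectEdges:
    def test_behavior_as_column_lands_in_positive_set(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 10))
        X[:, 4] = y
        sel = select_edges(X, y, alpha=0.01)
        assert 4 in sel.positive and 4 not in sel.negative

    def test_flipped_behavior_lands_in_negative_set(self, rng):
        y = rng.normal(size=30)
        X = rng.normal(size=(30, 10))
        X[:, 7] = -y
        sel = select_edges(X, y, alpha=0.01)
        assert 7 in sel.negative

    def test_constant_column_excluded_and_counted(self, rng):
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 5))
        X[:, 2] = 3.0
        sel = select_edges(X, y, alpha=0.5)
        assert sel.n_excluded_constant == 1
        assert 2 not in sel.positive | sel.negative

    def test_pvalues_match_scipy(self, rng):
        y = rng.normal(size=25)
        X = rng.normal(size=(25, 40))
        r, p, valid = _corr_with_pvals(X, y)
        for e in range(40):
            rs, ps = pearsonr(X[:, e], y)
            assert r[e] == pytest.approx(rs, abs=1e-12)
            assert p[e] == pytest.approx(ps, rel=1e-9)

    def test_requires_both_classes_for_binary(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="both classes"):
            select_edges(X, np.ones(10))


# ---------------------------------------------------------------------------
# fit_fold_model
# ---------------------------------------------------------------------------

class TestFoldModel:
    def test_exact_linear_relation_recovered(self, rng):
        X = rng.normal(size=(40, 6))
        sel = EdgeSelection(positive=frozenset({0, 2}), negative=frozenset({5}))
        y = X[:, [0, 2]].sum(axis=1)  # y equals the positive-sum feature
        model = fit_fold_model(X, y, sel, "arousal")
        assert np.allclose(model.predict(X), y, atol=1e-6)

    def test_separated_binary_fits_training_perfectly(self, rng):
        X = rng.normal(size=(30, 4))
        sel = EdgeSelection(positive=frozenset({1}), negative=frozenset())
        y = (X[:, 1] > 0).astype(float)  # perfectly separated by pos-sum
        model = fit_fold_model(X, y, sel, "memory")
        assert np.mean((model.predict(X) >= 0.5) == y) == 1.0

    def test_logistic_matches_statsmodels_on_benign_data(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(200, 3))
        sel = EdgeSelection(positive=frozenset({0}), negative=frozenset({1}))
        eta = 0.8 * X[:, 0] - 0.5 * X[:, 1]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_fold_model(X, y, sel, "memory")
        Z = model.features(X)
        ref = sm.Logit(y, Z).fit(disp=0)
        assert np.allclose(model.coef, ref.params, atol=1e-4)

    def test_empty_selection_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        sel = EdgeSelection(positive=frozenset(), negative=frozenset())
        with pytest.raises(ValueError, match="unpredictable"):
            fit_fold_model(X, X[:, 0], sel, "arousal")

    def test_in_sample_r2_near_small_sample_null(self, rng):
        """With random y, in-sample R^2 of the 2-feature fit concentrates
        near the analytic null mean q/(n-1)."""
        n, q, reps = 40, 2, 300
        r2 = []
        sel = EdgeSelection(positive=frozenset({0}), negative=frozenset({1}))
        for _ in range(reps):
            X = rng.normal(size=(n, 4))
            y = rng.normal(size=n)
            model = fit_fold_model(X, y, sel, "arousal")
            pred = model.predict(X)
            r2.append(np.corrcoef(pred, y)[0, 1] ** 2)
        expected = q / (n - 1)
        assert np.mean(r2) == pytest.approx(expected, abs=0.02)


# ---------------------------------------------------------------------------
# loto_cv against the naive reference (also the no-leakage check)
# ---------------------------------------------------------------------------

class TestLotoCV:
    @pytest.mark.parametrize("construct", ["arousal", "memory"])
    def test_matches_naive_per_fold_recomputation(self, small_problem,
                                                  construct):
        X, ya, ym = small_problem
        X = X[:60, :120]
        y = (ya if construct == "arousal" else ym)[:60]
        res = loto_cv(X, y, construct=construct, alpha=0.01)
        ref = naive_loto(X, y, construct, alpha=0.01)
        both = np.isfinite(res.predictions) & np.isfinite(ref)
        assert np.array_equal(np.isfinite(res.predictions), np.isfinite(ref))
        assert np.allclose(res.predictions[both], ref[both], atol=1e-6)

    def test_performance_matches_oracle_from_predictions(self, small_problem):
        X, ya, ym = small_problem
        res = loto_cv(X, ya, construct="arousal")
        ok = np.isfinite(res.predictions)
        assert res.performance == pytest.approx(
            np.corrcoef(res.predictions[ok], ya[ok])[0, 1])
        resm = loto_cv(X, ym, construct="memory")
        okm = np.isfinite(resm.predictions)
        acc = np.mean((resm.predictions[okm] >= 0.5) == ym[okm])
        assert resm.performance == pytest.approx(acc)

    def test_held_out_value_cannot_leak(self, small_problem):
        """Changing the held-out trial's behavior must not change its own
        prediction (selection and fit exclude it)."""
        X, ya, _ = small_problem
        X = X[:40, :80]
        y = ya[:40].copy()
        res = loto_cv(X, y, construct="arousal")
        k = 7
        y2 = y.copy()
        y2[k] = y2[k] + 2.0
        res2 = loto_cv(X, y2, construct="arousal")
        assert res.predictions[k] == pytest.approx(res2.predictions[k],
                                                   abs=1e-10)

    def test_two_trials_flagged_degenerate(self):
        X = np.random.default_rng(0).normal(size=(2, 6))
        res = loto_cv(X, np.array([1.0, 3.0]), construct="arousal", n_nodes=4)
        assert res.degenerate
        assert np.isnan(res.performance)


# ---------------------------------------------------------------------------
# permutation_test
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_perfect_signal_gets_minimal_p(self, rng):
        n, n_perm = 40, 50
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 20))
        X[:, 3] = y + 0.01 * rng.normal(size=n)
        # alpha generous enough that every null fold keeps a real selection,
        # so the null holds genuine cross-validated r values
        null, p = permutation_test(X, y, "arousal", alpha=0.3,
                                   n_perm=n_perm, seed=1)
        assert p == pytest.approx(1.0 / (n_perm + 1))

    def test_p_obeys_add_one_convention(self, rng):
        n = 25
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 30))
        null, p = permutation_test(X, y, "arousal", alpha=0.2, n_perm=40,
                                   seed=3)
        res = loto_cv(X, y, construct="arousal", alpha=0.2)
        scores = np.where(np.isfinite(null), null, -np.inf)
        expect = (1 + np.sum(scores >= res.performance)) / 41
        assert p == pytest.approx(expect)
        assert 0 < p <= 1

    def test_reproducible_under_seed(self, rng):
        y = rng.normal(size=20)
        X = rng.normal(size=(20, 15))
        n1, p1 = permutation_test(X, y, "arousal", alpha=0.3, n_perm=20, seed=9)
        n2, p2 = permutation_test(X, y, "arousal", alpha=0.3, n_perm=20, seed=9)
        assert np.array_equal(n1, n2, equal_nan=True) and p1 == p2

    def test_subject_blocked_shuffle_stays_within_blocks(self, rng):
        y = np.array([0, 0, 0, 10, 10, 10], dtype=float) + rng.normal(size=6) * 0.1
        X = rng.normal(size=(6, 8))
        subjects = np.array([0, 0, 0, 1, 1, 1])
        null, _ = permutation_test(X, y, "arousal", alpha=0.9, n_perm=10,
                                   seed=2, subjects=subjects)
        assert np.all(np.isfinite(null) | np.isnan(null))  # smoke: runs


# ---------------------------------------------------------------------------
# consensus and generalization
# ---------------------------------------------------------------------------

def _result_with_masks(pos, neg, n_nodes=5) -> CPMResult:
    pos, neg = np.asarray(pos, bool), np.asarray(neg, bool)
    n = pos.shape[0]
    return CPMResult(construct="arousal", performance=0.5,
                     predictions=np.zeros(n), observed=np.zeros(n),
                     pos_masks=pos, neg_masks=neg, alpha=0.01,
                     n_nodes=n_nodes)


class TestConsensus:
    def test_edge_on_every_fold_included_one_miss_excluded(self):
        pos = np.ones((4, 10), dtype=bool)
        pos[:, 1] = [True, True, False, True]  # missing on one fold
        neg = np.zeros((4, 10), dtype=bool)
        net = consensus_network(_result_with_masks(pos, neg))
        idx = net.positive_indices
        assert 0 in idx and 1 not in idx
        assert len(idx) == 9

    def test_consensus_subset_of_every_fold(self, coupled_matrix):
        X, _ = coupled_matrix
        res = loto_cv(X, construct="arousal")
        net = consensus_network(res)
        for k in range(res.pos_masks.shape[0]):
            sel = res.fold_selection(k)
            assert net.positive_indices <= sel.positive
            assert net.negative_indices <= sel.negative

    def test_recovers_planted_network(self, coupled_matrix):
        X, truth = coupled_matrix
        res = loto_cv(X, construct="arousal")
        net = consensus_network(res)
        tp = len(net.positive_edges & truth.planted_positive_edges)
        assert tp / max(len(net.positive_edges), 1) > 0.5
        assert tp / len(truth.planted_positive_edges) > 0.5


class TestGeneralize:
    def test_self_generalization_reduces_to_loto(self, small_problem):
        X, ya, _ = small_problem
        X = X[:50, :100]
        y = ya[:50]
        res = loto_cv(X, y, construct="arousal")
        gen = generalize(X, y, X, y, "arousal", "arousal")
        both = np.isfinite(res.predictions)
        assert np.array_equal(both, np.isfinite(gen.predictions))
        assert np.allclose(res.predictions[both], gen.predictions[both],
                           atol=1e-10)
        assert gen.performance == pytest.approx(res.performance)

    def test_mismatched_edge_manifests_rejected(self, rng):
        Xa = rng.normal(size=(10, 6))   # 4 nodes
        Xb = rng.normal(size=(10, 10))  # 5 nodes
        with pytest.raises(ValueError, match="manifest"):
            generalize(Xa, rng.normal(size=10), Xb, rng.normal(size=10),
                       "arousal", "arousal")
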