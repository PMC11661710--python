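"""Random survival forest: split statistic vs brute force, degenerate-tree
equivalence, prediction contracts, out-of-bag behavior."""

import numpy as np
import pytest

from esotwin.estimators import na_estimate
from esotwin.forest import (
    ForestParams,
    grow_forest,
    logrank_split_statistic,
    predict_curve,
)
from esotwin.forest import _best_split, _node_tables


def brute_force_logrank(times, events, left_mask):
    """Independent risk-set tabulation, one explicit loop per event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    left_mask = np.asarray(left_mask, bool)
    num = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        y = at_risk.sum()
        y_l = (at_risk & left_mask).sum()
        d = ((times == t) & (events == 1)).sum()
        d_l = ((times == t) & (events == 1) & left_mask).sum()
        num += d_l - y_l * d / y
        if y > 1:
            var += (y_l / y) * (1 - y_l / y) * ((y - d) / (y - 1)) * d
    return abs(num) / np.sqrt(var) if var > 0 else 0.0


def _random_instance(rng, n):
    times = rng.integers(1, 12, n).astype(float)  # deliberate heavy ties
    events = rng.integers(0, 2, n)
    if events.sum() == 0:
        events[rng.integers(n)] = 1
    mask = np.zeros(n, bool)
    mask[rng.choice(n, rng.integers(1, n), replace=False)] = True
    if mask.all():
        mask[0] = False
    return times, events, mask


class TestLogrankStatistic:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            t, e, m = _random_instance(rng, int(rng.integers(4, 26)))
            assert logrank_split_statistic(t, e, m) == pytest.approx(
                brute_force_logrank(t, e, m), abs=1e-10)

    def test_identical_groups_score_zero(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        m = np.array([True] * 3 + [False] * 3)
        assert logrank_split_statistic(t, e, m) == pytest.approx(0.0, abs=1e-12)

    def test_ordered_split_matches_oracle(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 1, 1])
        m = np.array([True, True, False, False])
        assert logrank_split_statistic(t, e, m) == pytest.approx(
            brute_force_logrank(t, e, m), abs=1e-12)

    def test_single_event_total(self):
        t = np.array([3.0, 5.0, 8.0])
        e = np.array([0, 1, 0])
        for m in ([True, False, False], [True, True, False]):
            assert logrank_split_statistic(t, e, m) == pytest.approx(
                brute_force_logrank(t, e, m), abs=1e-12)

    def test_degenerate_masks_rejected(self):
        with pytest.raises(ValueError):
            logrank_split_statistic([1.0, 2.0], [1, 1], [True, True])


class TestSplitFinder:
    def test_equals_exhaustive_maximization_on_small_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(8, 26))
            p = int(rng.integers(1, 4))
            X = rng.integers(0, 5, (n, p)).astype(float)
            t = rng.integers(1, 15, n).astype(float)
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            order, starts, ev, d, y = _node_tables(t, e)
            found = _best_split(X, t, e, order, starts, ev, d, y,
                                mtry=p, max_candidates=10_000,
                                rng=np.random.default_rng(0))
            # exhaustive scan over every feature and midpoint
            best_stat, best = 0.0, None
            for f in range(p):
                u = np.unique(X[:, f])
                for thr in (u[:-1] + u[1:]) / 2:
                    mask = X[:, f] <= thr
                    s = brute_force_logrank(t, e, mask)
                    if s > best_stat:
                        best_stat, best = s, (f, thr)
            if best is None:
                assert found is None
            else:
                f, thr = found
                got = brute_force_logrank(t, e, X[:, f] <= thr)
                assert got == pytest.approx(best_stat, abs=1e-10)


class TestDegenerateForest:
    def test_single_root_tree_is_pooled_nelson_aalen(self):
        t = np.array([2.0, 4.0, 4.0, 7.0])
        e = np.array([1, 1, 0, 1])
        X = np.zeros((4, 1))
        forest = grow_forest(
            X, t, e, ForestParams(ntree=1, nodesize=10, bootstrap=False), seed=0)
        curve = predict_curve(forest, X[0])
        te, H = na_estimate(t, e)
        np.testing.assert_array_equal(curve.times, te)
        np.testing.assert_array_equal(curve.survival, np.exp(-H))
        # hand-tabulated risk sets: H = 1/4, 1/4+1/3, 1/4+1/3+1
        np.testing.assert_allclose(
            curve.survival,
            np.exp(-np.array([1 / 4, 1 / 4 + 1 / 3, 1 / 4 + 1 / 3 + 1.0])))


class TestGrowForest:
    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            grow_forest(np.zeros((10, 2)), np.arange(1.0, 11.0),
                        np.zeros(10, int), ForestParams(ntree=2), seed=0)

    def test_missing_values_rejected(self):
        X = np.zeros((10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            grow_forest(X, np.arange(1.0, 11.0), np.ones(10, int),
                        ForestParams(ntree=2), seed=0)

    def test_no_hazard_before_first_event(self):
        rng = np.random.default_rng(0)
        n = 120
        X = rng.normal(size=(n, 3))
        t = rng.uniform(6.0, 60.0, n)
        e = rng.integers(0, 2, n)
        e[t.argmin()] = 1
        forest = grow_forest(X, t, e, ForestParams(ntree=20, nodesize=5), seed=1)
        curve = predict_curve(forest, X[0])
        first_event = t[e == 1].min()
        assert np.all(curve.survival[curve.times < first_event] == 1.0)
        # contract: monotone, bounded
        assert curve.survival[0] <= 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_predictions_invariant_to_tree_order(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        t = rng.exponential(20, 80) + 0.5
        e = rng.integers(0, 2, 80)
        e[0] = 1
        forest = grow_forest(X, t, e, ForestParams(ntree=30, nodesize=5), seed=3)
        H1 = forest.predict_cumhaz(X)
        forest.trees = forest.trees[::-1]
        np.testing.assert_allclose(forest.predict_cumhaz(X), H1, rtol=1e-12)

    def test_same_seed_reproduces_forest(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 2))
        t = rng.exponential(20, 60) + 0.5
        e = np.ones(60, int)
        f1 = grow_forest(X, t, e, ForestParams(ntree=10), seed=9)
        f2 = grow_forest(X, t, e, ForestParams(ntree=10), seed=9)
        np.testing.assert_array_equal(f1.predict_cumhaz(X), f2.predict_cumhaz(X))
        assert f1.oob_concordance_ == f2.oob_concordance_


class TestOOBConcordance:
    def test_null_signal_concordance_near_half(self):
        rng = np.random.default_rng(10)
        cs = []
        for _ in range(8):
            X = rng.normal(size=(400, 4))  # pure noise covariates
            t = rng.exponential(20, 400) + 0.1
            e = rng.integers(0, 2, 400)
            e[0] = 1
            f = grow_forest(X, t, e, ForestParams(ntree=40, nodesize=10), seed=int(rng.integers(2**31)))
            cs.append(f.oob_concordance_)
        assert abs(np.mean(cs) - 0.5) < 0.05

    def test_strong_signal_concordance_above_06(self):
        rng = np.random.default_rng(12)
        n = 800
        x = rng.integers(0, 2, n)
        X = np.column_stack([x, rng.normal(size=n)])
        lam = 0.02 * 3.0 ** x  # hazard ratio 3 across the binary covariate
        t = rng.exponential(1 / lam)
        c = rng.uniform(10, 120, n)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
        f = grow_forest(X, t, e, ForestParams(ntree=60, nodesize=10), seed=5)
        assert f.oob_concordance_ > 0.6

    def test_more_trees_stabilize_predictions(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(250, 3))
        t = rng.exponential(30 / (1 + 0.5 * (X[:, 0] > 0)), 250) + 0.1
        e = np.ones(250, int)
        row = X[:1]
        preds = {nt: [] for nt in (10, 80)}
        for nt in preds:
            for seed in range(8):
                f = grow_forest(X, t, e, ForestParams(ntree=nt, nodesize=10), seed=seed)
                s = f.predict_survival(row)[0]
                preds[nt].append(s[np.searchsorted(f.grid, 30.0)])
        assert np.var(preds[80]) < np.var(preds[10])


class TestOOBPrediction:
    def test_row_inbag_everywhere_raises(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(12, 2))
        t = rng.exponential(10, 12) + 0.5
        e = np.ones(12, int)
        f = grow_forest(X, t, e, ForestParams(ntree=1, nodesize=2), seed=0)
        inbag_row = int(np.flatnonzero(f.inbag[0])[0])
        with pytest.raises(ValueError, match=str(inbag_row)):
            f.predict_cumhaz(X[[inbag_row]], oob_rows=np.array([inbag_row]))


class TestCrossChecks:
    def test_logrank_statistic_squares_to_sksurv_chisq(self):
        """Independent oracle: the squared standardized log-rank statistic is
        the two-sample log-rank chi-square."""
        from sksurv.compare import compare_survival

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 60
            t = rng.exponential(20, n).round(1) + 0.5
            e = rng.integers(0, 2, n)
            e[0] = 1
            group = rng.integers(0, 2, n)
            if group.sum() in (0, n):
                group[0] = 1 - group[0]
            y = np.array([(bool(ev), tt) for ev, tt in zip(e, t)],
                         dtype=[("event", "?"), ("time", "<f8")])
            chi2, _ = compare_survival(y, group)
            ours = logrank_split_statistic(t, e, group == 0)
            assert ours**2 == pytest.approx(chi2, rel=1e-8)

    def test_comparable_discrimination_to_sksurv_forest(self):
        """Same data, same task: our RSF and scikit-survival's should reach
        similar out-of-sample concordance."""
        from lifelines.utils import concordance_index
        from sksurv.ensemble import RandomSurvivalForest

        rng = np.random.default_rng(22)
        n = 700
        X = rng.normal(size=(n, 4))
        lam = 0.02 * np.exp(0.7 * X[:, 0] + 0.4 * X[:, 1])
        t = rng.exponential(1 / lam)
        c = rng.uniform(5, 120, n)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
        tr, te = np.arange(0, 500), np.arange(500, n)
        ours = grow_forest(X[tr], t[tr], e[tr],
                           ForestParams(ntree=100, nodesize=10), seed=1)
        mort = ours.predict_cumhaz(X[te]).sum(axis=1)
        c_ours = concordance_index(t[te], -mort, e[te])
        y = np.array([(bool(ev), tt) for ev, tt in zip(e[tr], t[tr])],
                     dtype=[("event", "?"), ("time", "<f8")])
        ref = RandomSurvivalForest(n_estimators=100, min_samples_leaf=10,
                                   random_state=1, n_jobs=1).fit(X[tr], y)
        c_ref = concordance_index(t[te], -ref.predict(X[te]), e[te])
        assert c_ours > 0.65
        assert abs(c_ours - c_ref) < 0.05


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        from esotwin.forest import SurvivalForest

        rng = np.random.default_rng(23)
        X = rng.normal(size=(80, 3))
        t = rng.exponential(20, 80) + 0.5
        e = np.ones(80, int)
        f = grow_forest(X, t, e, ForestParams(ntree=15, nodesize=8), seed=2)
        path = tmp_path / "forest.json"
        f.to_json(path)
        g = SurvivalForest.from_json(path)
        np.testing.assert_allclose(g.predict_cumhaz(X), f.predict_cumhaz(X))
        assert g.oob_concordance_ == f.oob_concordance_
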