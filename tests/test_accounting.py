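"""RMST integration, gain/loss accounting, stratified box summaries."""

import numpy as np
import pytest

from esotwin.accounting import (
    DEFAULT_BENEFIT_THRESHOLD,
    boxplot_data,
    classify,
    gain_loss,
    plot_gain_loss,
    rmst,
    rmst_matrix,
    summarize_strata,
    survival_at,
)
from esotwin.estimators import SurvivalCurve


class TestRMST:
    def test_immortal_cohort(self):
        c = SurvivalCurve(np.array([130.0]), np.array([1.0]))
        assert rmst(c, 120.0) == 120.0

    def test_one_step_rectangle(self):
        c = SurvivalCurve(np.array([60.0]), np.array([0.0]))
        assert rmst(c, 120.0) == 60.0

    @pytest.mark.parametrize("lam", [0.005, 0.01, 0.05])
    def test_exponential_on_fine_grid_matches_closed_form(self, lam):
        t = np.arange(0.1, 130.0, 0.1)
        c = SurvivalCurve(t, np.exp(-lam * t))
        expected = (1 - np.exp(-lam * 120.0)) / lam
        assert rmst(c, 120.0) == pytest.approx(expected, abs=0.05)

    def test_monotone_in_pointwise_dominance(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 120, 30))
        s_hi = np.sort(rng.uniform(0.5, 1.0, 30))[::-1]
        s_lo = s_hi * 0.8
        hi = rmst(SurvivalCurve(t, s_hi), 120.0)
        lo = rmst(SurvivalCurve(t, s_lo), 120.0)
        assert hi >= lo

    def test_truncation_ignores_mass_beyond_tau(self):
        c1 = SurvivalCurve(np.array([10.0, 200.0]), np.array([0.5, 0.0]))
        c2 = SurvivalCurve(np.array([10.0]), np.array([0.5]))
        assert rmst(c1, 60.0) == rmst(c2, 60.0)


class _FakeTwins:
    def __init__(self, grid, surv0, surv1, pt, pn, tau=120.0):
        import pandas as pd
        from esotwin.accounting import rmst_matrix as rm
        self.grid = grid
        self.surv0, self.surv1 = surv0, surv1
        self.tau = tau
        r0 = rm(grid, surv0, tau)
        r1 = rm(grid, surv1, tau)
        self.table = pd.DataFrame({
            "id": [f"p{i}" for i in range(len(pt))],
            "treatment": 0, "pT": pt, "pN": pn,
            "rmst_eso": r0, "rmst_eso_plus": r1, "delta": r1 - r0})

    @property
    def delta(self):
        return self.table["delta"].to_numpy(float)


def _twins_with_deltas(deltas, pt=None, pn=None):
    """Twin table whose per-patient deltas equal ``deltas`` exactly."""
    deltas = np.asarray(deltas, float)
    n = len(deltas)
    grid = np.array([60.0])
    surv0 = np.full((n, 1), 0.5)
    # rmst = 60 + 60*s on [0,120], so delta = 60 * (s1 - s0)
    surv1 = surv0 + deltas[:, None] / 60.0
    pt = pt if pt is not None else ["T2"] * n
    pn = pn if pn is not None else ["N0"] * n
    return _FakeTwins(grid, surv0, surv1, pt, pn)


class TestGainLoss:
    def test_identical_curves_zero(self):
        t = _twins_with_deltas([0.0, 0.0])
        np.testing.assert_allclose(gain_loss(t), 0.0)

    def test_dominating_curve_positive(self):
        t = _twins_with_deltas([5.0, 12.0])
        assert (gain_loss(t) > 0).all()

    def test_swap_negates(self):
        t = _twins_with_deltas([3.0, -7.0])
        swapped = _FakeTwins(t.grid, t.surv1, t.surv0,
                             t.table["pT"], t.table["pN"])
        np.testing.assert_allclose(gain_loss(swapped), -gain_loss(t))

    def test_mixed_tau_rejected(self):
        a = _twins_with_deltas([1.0])
        b = _twins_with_deltas([1.0])
        b.tau = 60.0
        with pytest.raises(ValueError, match="mixed"):
            gain_loss([a, b])


class TestClassification:
    def test_median_zero_is_insignificant(self):
        t = _twins_with_deltas([-2.0, -1.0, 0.0, 1.0, 2.0])
        (s,) = summarize_strata(t)
        assert s.median == 0.0
        assert s.benefit_class == "insignificant benefit"

    def test_detriment_matches_published_reading(self):
        # an 11-month median loss is a detriment cell
        assert classify(-11.0) == "detriment"

    def test_meaningful_benefit_matches_published_reading(self):
        # an 8.2-month median gain clears the 4-month threshold
        assert classify(8.2, threshold=4.0) == "meaningful benefit"

    def test_threshold_boundary(self):
        assert classify(DEFAULT_BENEFIT_THRESHOLD) == "meaningful benefit"
        assert classify(DEFAULT_BENEFIT_THRESHOLD - 1e-9) == "insignificant benefit"


class TestSummarizeStrata:
    def _mixed_twins(self, seed=0, n=200):
        rng = np.random.default_rng(seed)
        pt = rng.choice(["T1", "T2", "T3"], n)
        pn = rng.choice(["N0", "N1", "N3"], n)
        return _twins_with_deltas(rng.normal(0, 5, n), pt, pn)

    def test_counts_partition_cohort(self):
        t = self._mixed_twins()
        summaries = summarize_strata(t)
        assert sum(s.n for s in summaries) == len(t.table)

    def test_quartile_ordering_and_whiskers(self):
        t = self._mixed_twins(seed=3)
        for s in summarize_strata(t):
            assert s.q1 <= s.median <= s.q3
            assert s.whisker_lo <= s.q1 and s.q3 <= s.whisker_hi

    def test_collapsed_pn_groups(self):
        t = self._mixed_twins(seed=4)
        collapsed = summarize_strata(t, collapse_pn=True)
        assert set(s.pn for s in collapsed) <= {"N0", "N+"}
        assert sum(s.n for s in collapsed) == len(t.table)

    def test_empty_stratum_absent(self):
        t = _twins_with_deltas([1.0, 2.0], pt=["T1", "T1"], pn=["N0", "N0"])
        summaries = summarize_strata(t)
        assert [(s.pt, s.pn) for s in summaries] == [("T1", "N0")]

    def test_five_year_survival_is_curve_at_60_months(self):
        t = _twins_with_deltas([6.0, 6.0])
        (s,) = summarize_strata(t)
        assert s.surv5_eso == pytest.approx(50.0)
        assert s.surv5_eso_plus == pytest.approx(60.0)


class TestBoxplotData:
    def test_width_proportional_to_n(self):
        t = _twins_with_deltas(
            list(np.arange(100)) + list(np.arange(50)),
            pt=["T1"] * 100 + ["T2"] * 50, pn=["N0"] * 150)
        boxes = {b["pT"]: b for b in boxplot_data(summarize_strata(t))}
        assert boxes["T1"]["width"] / boxes["T2"]["width"] == pytest.approx(2.0)

    def test_degenerate_all_equal(self):
        t = _twins_with_deltas([4.0] * 10)
        (b,) = boxplot_data(summarize_strata(t))
        assert b["q1"] == b["median"] == b["q3"] == pytest.approx(4.0)
        assert len(b["outliers"]) == 0

    def test_outlier_count_matches_direct_recount(self):
        rng = np.random.default_rng(9)
        deltas = np.concatenate([rng.normal(0, 2, 80), [40.0, -35.0]])
        t = _twins_with_deltas(deltas)
        (b,) = boxplot_data(summarize_strata(t))
        q1, q3 = np.percentile(deltas, [25, 75])
        iqr = q3 - q1
        direct = np.sum((deltas < q1 - 1.5 * iqr) | (deltas > q3 + 1.5 * iqr))
        assert len(b["outliers"]) == direct

    def test_plot_file_written(self, tmp_path):
        t = _twins_with_deltas(
            np.linspace(-5, 5, 40), pt=["T2"] * 40, pn=["N0"] * 40)
        path = tmp_path / "box.svg"
        plot_gain_loss(summarize_strata(t), path)
        assert path.exists() and path.stat().st_size > 0


class TestSurvivalAt:
    def test_right_continuous_step(self):
        grid = np.array([30.0, 60.0])
        surv = np.array([[0.8, 0.4]])
        assert survival_at(grid, surv, 59.9)[0] == 0.8
        assert survival_at(grid, surv, 60.0)[0] == 0.4
        assert survival_at(grid, surv, 10.0)[0] == 1.0
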