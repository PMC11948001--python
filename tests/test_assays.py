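"""Assay statistics: ELDA, H-score, subtype calls, KM/log-rank, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gliores import synthetic
from gliores.assays import (LimitingDilutionModel, _dilution_loglik,
                            call_subtype, elda_compare, elda_fit, h_score,
                            km_logrank, logrank_chi2, relative_signal)


def dilution_table(rows):
    return pd.DataFrame(rows, columns=["cells_per_well", "wells_tested",
                                       "wells_responding"])


class TestEldaFit:
    def test_single_row_closed_form(self):
        # 8/16 wells at 10 cells: 1 - exp(-10 f) = 0.5  =>  f = ln2 / 10
        est = elda_fit(dilution_table([(10, 16, 8)]))
        assert est.f_hat == pytest.approx(np.log(2) / 10, abs=1e-6)

    def test_all_negative_boundary(self):
        est = elda_fit(dilution_table([(0, 16, 0), (5, 16, 0), (20, 16, 0)]))
        assert est.boundary and est.f_hat == 0.0
        assert est.ci_upper == pytest.approx(-np.log(0.05) / (16 * 25))

    def test_all_positive_boundary(self):
        est = elda_fit(dilution_table([(5, 16, 16), (20, 16, 16)]))
        assert est.boundary and est.f_hat == 1.0 and est.ci_lower > 0

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        grid = np.logspace(-4, 0, 10_000)
        checked = 0
        for _ in range(100):
            f = 10 ** rng.uniform(-3, -0.5)
            tab = synthetic.gen_dilution_assay(
                f, doses=(0, 1, 5, 10, 20, 50), n_wells=16,
                seed=int(rng.integers(2 ** 31)))
            pos = tab[tab.cells_per_well > 0]
            if pos.wells_responding.sum() == 0 or \
                    (pos.wells_responding == pos.wells_tested).all():
                continue
            est = elda_fit(tab)
            x = pos.cells_per_well.to_numpy(float)
            n = pos.wells_tested.to_numpy(float)
            k = pos.wells_responding.to_numpy(float)
            p = np.clip(1.0 - np.exp(-np.outer(grid, x)), 1e-300, 1 - 1e-15)
            ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=1)
            f_grid = grid[ll.argmax()]
            assert abs(est.f_hat - f_grid) / f_grid <= 0.01
            checked += 1
        assert checked >= 80

    def test_wald_ci_coverage_near_nominal(self):
        hits = 0
        n_sim = 400
        for i in range(n_sim):
            tab = synthetic.gen_dilution_assay(
                0.1, doses=(0, 1, 5, 10, 20, 50), n_wells=16, seed=70_000 + i)
            est = elda_fit(tab)
            hits += est.ci_lower <= 0.1 <= est.ci_upper
        assert 0.92 <= hits / n_sim <= 0.98

    def test_profile_ci_contains_estimate(self):
        est = elda_fit(dilution_table([(1, 16, 2), (5, 16, 7), (10, 16, 11),
                                       (20, 16, 14)]), ci_method="profile")
        assert est.ci_lower < est.f_hat < est.ci_upper

    def test_dose_zero_with_responders_rejected(self):
        with pytest.raises(ValueError):
            elda_fit(dilution_table([(0, 16, 2), (10, 16, 8)]))

    def test_sklearn_wrapper(self):
        model = LimitingDilutionModel().fit(dilution_table([(10, 16, 8)]))
        assert model.frequency_ == pytest.approx(np.log(2) / 10, abs=1e-6)
        assert model.ci_[0] < model.frequency_ < model.ci_[1]


class TestEldaCompare:
    def test_identical_tables_give_null(self):
        t = dilution_table([(1, 16, 2), (10, 16, 10), (50, 16, 16)])
        out = elda_compare(t, t)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-6)
        assert out["p"] == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_in_arguments(self):
        a = dilution_table([(1, 16, 3), (10, 16, 12)])
        b = dilution_table([(1, 16, 1), (10, 16, 5)])
        assert elda_compare(a, b)["chi2"] == pytest.approx(
            elda_compare(b, a)["chi2"])

    def test_tenfold_frequency_difference_is_powerful(self):
        hits = 0
        for i in range(40):
            a = synthetic.gen_dilution_assay(0.2, doses=(0, 1, 5, 10, 20, 50),
                                             n_wells=16, seed=80_000 + i)
            b = synthetic.gen_dilution_assay(0.02, doses=(0, 1, 5, 10, 20, 50),
                                             n_wells=16, seed=90_000 + i)
            hits += elda_compare(a, b)["p"] < 0.001
        assert hits >= 38


class TestHScore:
    def test_pure_strong_scores_300(self):
        assert h_score(0.0, 0.0, 1.0) == 300.0

    def test_all_negative_scores_zero(self):
        assert h_score(0.0, 0.0, 0.0, 1.0) == 0.0

    def test_hand_worked_mixture(self):
        assert h_score(0.5, 0.3, 0.2) == pytest.approx(170.0)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_bounded_and_linear(self, raw):
        total = sum(raw)
        if total == 0:
            raw = [1.0, 0.0, 0.0, 0.0]
            total = 1.0
        w, m, s, n = (v / total for v in raw)
        score = h_score(w, m, s, n)
        assert 0.0 <= score <= 300.0
        assert score == pytest.approx(100 * w + 200 * m + 300 * s)

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError):
            h_score(0.9, 0.9, 0.9)


class TestCallSubtype:
    def test_extreme_samples_called_correctly(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 1, size=(10, 4)),
                          columns=["CD44", "YKL40", "SOX2", "OLIG2"])
        df.loc[0, ["CD44", "YKL40"]] = 20.0
        df.loc[0, ["SOX2", "OLIG2"]] = 0.0
        out = call_subtype(df)
        assert out.loc[0, "subtype"] == "MES"

    def test_exact_tie_goes_to_pn_and_is_flagged(self):
        df = pd.DataFrame({
            "CD44": [1.0, 2.0, 3.0], "YKL40": [1.0, 2.0, 3.0],
            "SOX2": [1.0, 2.0, 3.0], "OLIG2": [1.0, 2.0, 3.0]})
        out = call_subtype(df)
        assert (out["subtype"] == "PN").all() and out["tie"].all()

    def test_planted_two_population_panel_concordance(self):
        rng = np.random.default_rng(3)
        n = 100
        is_mes = rng.random(n) < 0.5
        df = pd.DataFrame({
            "CD44": np.where(is_mes, 8.0, 4.0) + rng.normal(0, 0.8, n),
            "YKL40": np.where(is_mes, 8.0, 4.0) + rng.normal(0, 0.8, n),
            "SOX2": np.where(is_mes, 4.0, 8.0) + rng.normal(0, 0.8, n),
            "OLIG2": np.where(is_mes, 4.0, 8.0) + rng.normal(0, 0.8, n)})
        out = call_subtype(df)
        concord = (out["subtype"] == np.where(is_mes, "MES", "PN")).mean()
        assert concord >= 0.95

    def test_zero_variance_marker_rejected(self):
        df = pd.DataFrame({"CD44": [1, 1], "YKL40": [1, 2], "SOX2": [2, 1],
                           "OLIG2": [1, 2]})
        with pytest.raises(ValueError):
            call_subtype(df)


class TestKmLogrank:
    def test_identical_groups_give_null(self):
        times = [1, 2, 3, 4, 1, 2, 3, 4]
        events = [1] * 8
        groups = ["A"] * 4 + ["B"] * 4
        out = km_logrank(times, events, groups)
        assert out.chi2 == pytest.approx(0.0, abs=1e-12)
        assert out.p == pytest.approx(1.0)

    def test_hand_computed_small_table(self):
        # A: deaths at 1, 2 (n=2); B: deaths at 3, 4 (n=2); chi2 = 49/17
        chi2, _ = logrank_chi2([1, 2, 3, 4], [1, 1, 1, 1],
                               ["A", "A", "B", "B"])
        assert chi2 == pytest.approx(49.0 / 17.0, rel=1e-12)

    def test_km_curves_match_product_limit_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(4, 25))
            times = np.round(rng.exponential(5, n), 0) + 1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            groups = ["A"] * n + ["B"] * 3
            times = np.r_[times, [1.0, 2.0, 3.0]]
            events = np.r_[events, [1, 1, 1]]
            out = km_logrank(times, events, groups)
            curve = out.km_curves["A"]["A"]
            # hand-rolled product-limit estimate on group A
            ta, ea = times[:n], events[:n]
            uniq = np.unique(ta[ea == 1])
            surv = 1.0
            for t in uniq:
                at_risk = (ta >= t).sum()
                d = ((ta == t) & (ea == 1)).sum()
                surv *= 1.0 - d / at_risk
                assert curve.loc[t] == pytest.approx(surv, rel=1e-12)
            values = curve.to_numpy()
            assert values[0] == pytest.approx(1.0)
            assert (np.diff(values) <= 1e-12).all()

    def test_agrees_with_lifelines_statistic(self):
        from lifelines.statistics import logrank_test
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, m = int(rng.integers(5, 30)), int(rng.integers(5, 30))
            ta = np.round(rng.exponential(10, n)) + 1
            tb = np.round(rng.exponential(6, m)) + 1
            ea = rng.integers(0, 2, n)
            eb = rng.integers(0, 2, m)
            if ea.sum() == 0 or eb.sum() == 0:
                continue
            mine, _ = logrank_chi2(np.r_[ta, tb], np.r_[ea, eb],
                                   np.r_[["A"] * n, ["B"] * m])
            ref = logrank_test(ta, tb, event_observed_A=ea,
                               event_observed_B=eb).test_statistic
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2], [1, 1], ["A", "A"])


class TestRelativeSignal:
    def test_constant_series_maps_to_ones(self):
        np.testing.assert_allclose(relative_signal([7, 7, 7]), 1.0)

    def test_hand_example(self):
        np.testing.assert_allclose(relative_signal([100, 200, 400]),
                                   [1.0, 2.0, 4.0])

    def test_singleton(self):
        np.testing.assert_allclose(relative_signal([3.5]), [1.0])

    def test_nonpositive_first_value_rejected(self):
        with pytest.raises(ValueError):
            relative_signal([0.0, 1.0])
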