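"""Signature derivation: stratification, DE, volcano filter, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gliores import io, signature, synthetic
from gliores.signature import GeneSignature


def make_cohort(times, status=None, therapy=None):
    n = len(times)
    return pd.DataFrame({
        "survival_time": times,
        "vital_status": status or ["dead"] * n,
        "therapy": therapy or ["chemoradiotherapy"] * n,
    }, index=[f"S{i}" for i in range(n)])


class TestStratifyBySurvival:
    def test_median_split_with_ties_to_sensitive(self):
        lab = signature.stratify_by_survival(make_cohort([2, 4, 6, 8]))
        assert list(lab["group"]) == ["resistant", "resistant",
                                      "sensitive", "sensitive"]
        # a sample exactly at the cutoff is sensitive
        lab2 = signature.stratify_by_survival(make_cohort([2, 5, 8]))
        assert lab2.loc["S1", "group"] == "sensitive"

    def test_all_alive_is_empty_after_restriction(self):
        with pytest.raises(ValueError):
            signature.stratify_by_survival(
                make_cohort([5, 6, 7], status=["alive"] * 3))

    def test_degenerate_identical_times(self):
        with pytest.raises(ValueError):
            signature.stratify_by_survival(make_cohort([3, 3, 3]))

    def test_quantile_rule(self):
        lab = signature.stratify_by_survival(
            make_cohort([1, 2, 3, 4, 5, 6, 7, 8, 9, 10]), rule="quantile",
            q=0.3)
        assert (lab["group"] == "resistant").sum() == 3


class TestStratifyByApoptosis:
    @staticmethod
    def make(control, rt, tmz, line="L0"):
        rows = []
        for cond, reps in (("control", control), ("RT", rt), ("TMZ", tmz)):
            rows += [(line, cond, i, v) for i, v in enumerate(reps)]
        return pd.DataFrame(rows, columns=["line", "condition", "replicate",
                                           "apoptosis_fraction"])

    def test_no_treatment_effect_is_resistant(self):
        t = self.make([0.05, 0.05, 0.05], [0.05, 0.05, 0.05],
                      [0.05, 0.05, 0.05])
        assert signature.stratify_by_apoptosis(t)["label"].iloc[0] == "resistant"

    def test_strong_increase_is_sensitive(self):
        t = self.make([0.04, 0.05, 0.06], [0.58, 0.60, 0.62],
                      [0.05, 0.05, 0.05])
        out = signature.stratify_by_apoptosis(t)
        assert out["label"].iloc[0] == "sensitive"
        # oracle: scipy t-test agrees this is overwhelming
        _, p = stats.ttest_ind([0.58, 0.60, 0.62], [0.04, 0.05, 0.06])
        assert p < 1e-4 and out["p_RT"].iloc[0] == pytest.approx(p)

    def test_alpha_zero_makes_everything_resistant(self):
        t = self.make([0.05, 0.05], [0.9, 0.9], [0.9, 0.9])
        assert signature.stratify_by_apoptosis(t, alpha=0.0)["label"]\
            .iloc[0] == "resistant"

    def test_missing_control_rejected(self):
        t = self.make([0.05, 0.05], [0.9, 0.9], [0.9, 0.9])
        with pytest.raises(ValueError):
            signature.stratify_by_apoptosis(t[t["condition"] != "control"])


def _labelled_matrix(n_per_group=100, n_genes=50, effect_gene="G5",
                     effect=1.0, sigma=0.2, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{i}" for i in range(2 * n_per_group)]
    data = rng.normal(5.0, sigma, size=(n_genes, 2 * n_per_group))
    data[genes.index(effect_gene), :n_per_group] += effect
    expr = io.ExpressionMatrix(
        pd.DataFrame(np.clip(data, 0, None), index=genes, columns=samples),
        scale="lognorm")
    labels = pd.Series(["resistant"] * n_per_group + ["sensitive"] * n_per_group,
                       index=samples)
    return expr, labels


class TestDifferentialExpression:
    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_planted_gene_detected(self, method):
        expr, labels = _labelled_matrix()
        de = signature.differential_expression(expr, labels, method=method)
        assert 0.8 <= de.loc["G5", "log2fc"] <= 1.2
        assert de.loc["G5", "fdr"] < 0.05

    def test_null_matrix_has_no_discoveries(self):
        expr, labels = _labelled_matrix(effect=0.0, seed=1)
        de = signature.differential_expression(expr, labels)
        assert np.abs(de["log2fc"]).max() < 0.2
        assert (de["fdr"] <= 0.05).mean() <= 0.05

    def test_label_swap_negates_log2fc_exactly(self):
        expr, labels = _labelled_matrix(seed=2)
        de = signature.differential_expression(expr, labels)
        swapped = labels.map({"resistant": "sensitive",
                              "sensitive": "resistant"})
        de2 = signature.differential_expression(expr, swapped)
        np.testing.assert_array_equal(de["log2fc"].to_numpy(),
                                      -de2["log2fc"].to_numpy())

    def test_welch_matches_scipy_oracle(self):
        expr, labels = _labelled_matrix(n_per_group=10, n_genes=20, seed=3)
        de = signature.differential_expression(expr, labels)
        a = expr.data.loc["G7", labels[labels == "resistant"].index]
        b = expr.data.loc["G7", labels[labels == "sensitive"].index]
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert de.loc["G7", "p"] == pytest.approx(p, rel=1e-9)

    def test_too_few_samples_rejected(self):
        expr, labels = _labelled_matrix(n_per_group=2)
        labels.iloc[0] = "sensitive"
        with pytest.raises(ValueError):
            signature.differential_expression(expr, labels)


class TestVolcanoFilter:
    @staticmethod
    def de_table():
        return pd.DataFrame({
            "log2fc": [0.5, 0.49, -0.8, 2.0, 0.7],
            "p": [0.05, 0.001, 0.01, 0.2, 0.01],
        }, index=["boundary", "below_lfc", "down", "high_p", "hit"])

    def test_inclusive_boundaries(self):
        sig = signature.volcano_filter(self.de_table(), 0.5, 0.05)
        assert "boundary" in sig and "hit" in sig
        assert "below_lfc" not in sig and "high_p" not in sig

    def test_sensitive_direction(self):
        sig = signature.volcano_filter(self.de_table(), 0.5, 0.05,
                                       direction="sensitive-up")
        assert sig.genes == ("down",)

    def test_invalid_direction(self):
        with pytest.raises(ValueError):
            signature.volcano_filter(self.de_table(), 0.5, 0.05,
                                     direction="sideways")


class TestIntersectSignatures:
    def test_subset_and_disjoint(self):
        a = GeneSignature(("x", "y"), "resistant-up")
        b = GeneSignature(("x", "y", "z"), "resistant-up")
        assert signature.intersect_signatures(a, b).genes == ("x", "y")
        c = GeneSignature(("q",), "resistant-up")
        assert signature.intersect_signatures(a, c).genes == ()

    def test_direction_mismatch_empties(self):
        a = GeneSignature(("x",), "resistant-up")
        b = GeneSignature(("x",), "sensitive-up")
        assert signature.intersect_signatures(a, b).genes == ()


class TestCorrelateGene:
    def test_self_and_negation(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(5, 1, size=(2, 30)),
                            index=["a", "b"], columns=[f"S{i}" for i in range(30)])
        data.loc["b"] = 10 - data.loc["a"]
        expr = io.ExpressionMatrix(data.clip(lower=0), scale="lognorm")
        out = signature.correlate_gene(expr, "a", ["a", "b"])
        assert out.loc["a", "r"] == pytest.approx(1.0)
        assert out.loc["b", "r"] == pytest.approx(-1.0)

    def test_latent_factor_correlation_matches_mc_oracle(self):
        loading, n = 0.9, 200
        rng = np.random.default_rng(1)
        # Monte-Carlo oracle for the expected r of two loading-0.9 children
        sims = []
        for _ in range(300):
            f = rng.normal(size=n)
            x = loading * f + np.sqrt(1 - loading ** 2) * rng.normal(size=n)
            y = loading * f + np.sqrt(1 - loading ** 2) * rng.normal(size=n)
            sims.append(np.corrcoef(x, y)[0, 1])
        expected, se = np.mean(sims), np.std(sims)
        f = rng.normal(size=n)
        x = 5 + loading * f + np.sqrt(1 - loading ** 2) * rng.normal(size=n)
        y = 5 + loading * f + np.sqrt(1 - loading ** 2) * rng.normal(size=n)
        expr = io.ExpressionMatrix(
            pd.DataFrame([x, y], index=["a", "b"],
                         columns=[f"S{i}" for i in range(n)]).clip(lower=0),
            scale="lognorm")
        r = signature.correlate_gene(expr, "a", ["b"]).loc["b", "r"]
        assert abs(r - expected) < 3 * se

    def test_zero_variance_rejected(self):
        data = pd.DataFrame({"S0": [1.0, 2.0], "S1": [1.0, 3.0],
                             "S2": [1.0, 4.0]}, index=["flat", "var"])
        expr = io.ExpressionMatrix(data, scale="lognorm")
        with pytest.raises(ValueError):
            signature.correlate_gene(expr, "flat", ["var"])


class TestPrerankedEnrichment:
    def test_top_k_geneset_scores_highest(self):
        rng = np.random.default_rng(0)
        stats_ = pd.Series(np.sort(rng.normal(size=100))[::-1],
                           index=[f"G{i}" for i in range(100)])
        top = [f"G{i}" for i in range(10)]
        res = signature.preranked_enrichment(stats_, top, n_perm=200, seed=1)
        assert res["es"] > 0
        for s in range(5):
            rand = list(rng.choice(stats_.index, size=10, replace=False))
            other = signature.preranked_enrichment(stats_, rand, n_perm=50,
                                                   seed=s)
            assert res["es"] >= other["es"]
        assert res["p"] < 0.05

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(150)]
        ps = []
        for rep in range(120):
            stats_ = pd.Series(rng.normal(size=150), index=genes)
            sel = list(rng.choice(genes, size=12, replace=False))
            ps.append(signature.preranked_enrichment(stats_, sel, n_perm=99,
                                                     seed=rep)["p"])
        assert 0.35 < np.mean(ps) < 0.65
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_zero_permutations_rejected(self):
        stats_ = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            signature.preranked_enrichment(stats_, ["a"], n_perm=0)

    def test_disjoint_geneset_rejected(self):
        stats_ = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError):
            signature.preranked_enrichment(stats_, ["zzz"], n_perm=10)
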