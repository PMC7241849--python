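"""Feature engineering: normalization, canopy, quantile aggregation, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microvoe as mv
from microvoe.errors import ConfigurationError
from microvoe.features import filter_features, univariate_associations

from conftest import threshold_cluster_oracle, two_block_matrix


class TestNormalizeCounts:
    def test_hand_computed_example(self):
        counts = pd.DataFrame([[10, 10, 10]], index=["s1"], columns=list("abc"))
        lengths = pd.Series([100, 200, 400], index=list("abc"))
        out = mv.normalize_counts(counts, lengths)
        np.testing.assert_allclose(out.loc["s1"], [4 / 7, 2 / 7, 1 / 7])

    def test_single_gene_and_scale_invariance(self):
        counts = pd.DataFrame([[5], [50]], index=["s1", "s2"], columns=["g"])
        out = mv.normalize_counts(counts, pd.Series([123], index=["g"]))
        np.testing.assert_allclose(out["g"], 1.0)
        counts2 = pd.DataFrame([[3, 9], [6, 18]], index=["s1", "s2"], columns=["g", "h"])
        out2 = mv.normalize_counts(counts2, pd.Series([10, 20], index=["g", "h"]))
        pd.testing.assert_series_equal(out2.loc["s1"], out2.loc["s2"], check_names=False)

    def test_all_zero_sample_names_sample(self):
        counts = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"], columns=["g", "h"])
        with pytest.raises(ConfigurationError, match="empty"):
            mv.normalize_counts(counts, pd.Series([10, 10], index=["g", "h"]))


class TestCanopy:
    def test_two_planted_blocks_recovered(self):
        table = two_block_matrix(seed=0)
        asg = mv.canopy_cluster(table)
        groups = [frozenset(m) for m in asg.groups().values()]
        expected = threshold_cluster_oracle(table)
        assert sorted(groups) == expected
        assert len(groups) == 2

    def test_identical_profiles_single_group(self):
        rng = np.random.default_rng(1)
        prof = rng.random(20)
        table = pd.DataFrame({f"g{i}": prof for i in range(6)})
        asg = mv.canopy_cluster(table)
        groups = asg.groups()
        assert len(groups) == 1
        assert len(next(iter(groups.values()))) == 6

    def test_uncorrelated_gene_dropped_as_singleton(self):
        table = two_block_matrix(seed=2)
        rng = np.random.default_rng(99)
        table["lone"] = rng.normal(0, 1, len(table))
        corr = table.corr()["lone"].drop("lone").abs()
        assert corr.max() < 0.5  # genuinely uncorrelated
        asg = mv.canopy_cluster(table)
        assert "lone" not in asg.mapping

    def test_oracle_agreement_rate(self):
        agree = 0
        n_seeds = 30
        for seed in range(n_seeds):
            table = two_block_matrix(seed=seed)
            asg = mv.canopy_cluster(table)
            got = sorted(frozenset(m) for m in asg.groups().values())
            if got == threshold_cluster_oracle(table):
                agree += 1
        assert agree / n_seeds >= 0.95

    def test_fewer_than_two_samples_error(self):
        table = pd.DataFrame([[0.5, 0.5]], columns=["a", "b"])
        with pytest.raises(ConfigurationError):
            mv.canopy_cluster(table)

    def test_every_group_at_least_two_genes(self, gene_data):
        genes, _ = gene_data
        asg = mv.canopy_cluster(genes)
        assert all(len(m) >= 2 for m in asg.groups().values())


class TestAggregateQuantile:
    def test_hand_computed_linear_interpolation(self):
        table = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["s"], columns=list("abcd"))
        out = mv.aggregate_quantile(table, {"G": list("abcd")}, q=0.75)
        assert out.loc["s", "G"] == pytest.approx(0.325)

    def test_constant_and_singleton_groups(self):
        table = pd.DataFrame([[0.2, 0.2, 0.7]], index=["s"], columns=list("abc"))
        out = mv.aggregate_quantile(table, {"G": ["a", "b"], "H": ["c"]})
        assert out.loc["s", "G"] == pytest.approx(0.2)
        assert out.loc["s", "H"] == pytest.approx(0.7)

    def test_empty_group_error(self):
        table = pd.DataFrame([[0.5]], columns=["a"])
        with pytest.raises(ConfigurationError):
            mv.aggregate_quantile(table, {"G": []})

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_member_abundance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((3, 5))
        table = pd.DataFrame(vals, columns=list("abcde"))
        out1 = mv.aggregate_quantile(table, {"G": list("abcde")})
        bumped = table.copy()
        j = rng.integers(0, 5)
        bumped.iloc[:, j] = bumped.iloc[:, j] + rng.random()
        out2 = mv.aggregate_quantile(bumped, {"G": list("abcde")})
        assert (out2["G"] >= out1["G"] - 1e-12).all()


def _random_table(rng, n, p, prefix="f"):
    return pd.DataFrame(
        rng.random((n, p)), columns=[f"{prefix}{j:04d}" for j in range(p)]
    )


class TestFilterFeatures:
    def test_rule_all_when_few_features(self):
        rng = np.random.default_rng(0)
        table = _random_table(rng, 50, 8)
        y = pd.Series(rng.normal(0, 1, 50), index=table.index)
        rep = filter_features(table, y, max_features=1000)
        assert rep.rule == "all"
        assert rep.selected == list(table.columns)

    def test_rule_coef_top_when_many_significant(self):
        # target built from many features: most are significant
        rng = np.random.default_rng(1)
        table = _random_table(rng, 120, 30)
        y = table.sum(axis=1) + rng.normal(0, 0.2, 120)
        rep = filter_features(table, y, max_features=10, task="regression")
        assert rep.rule == "coef-top"
        assert len(rep.selected) == 10
        # selected are the largest |coef| among significant
        sig = rep.table[rep.table.p_value < 0.05]
        top = sig["coef"].abs().sort_values(ascending=False).index[:10]
        assert set(rep.selected) == set(top)

    def test_rule_p_top_when_few_significant(self):
        rng = np.random.default_rng(2)
        table = _random_table(rng, 60, 30)
        y = pd.Series(rng.normal(0, 1, 60), index=table.index)  # null target
        rep = filter_features(table, y, max_features=12, task="regression")
        assert rep.rule == "p-top"
        assert len(rep.selected) == 12
        assert rep.selected == rep.table["p_value"].sort_values(kind="mergesort").index[:12].tolist()

    def test_train_only_no_test_leakage(self):
        rng = np.random.default_rng(3)
        table = _random_table(rng, 80, 20)
        y = pd.Series(rng.normal(0, 1, 80), index=table.index)
        train = table.index[:60]
        rep1 = filter_features(table.loc[train], y.loc[train], max_features=5)
        corrupted = table.copy()
        corrupted.iloc[60:, :] = 1e6  # corrupt the held-out rows
        rep2 = filter_features(corrupted.loc[train], y.loc[train], max_features=5)
        assert rep1.selected == rep2.selected
        pd.testing.assert_frame_equal(rep1.table, rep2.table)

    def test_linear_pvalues_match_scipy(self):
        rng = np.random.default_rng(4)
        table = _random_table(rng, 40, 6)
        y = pd.Series(rng.normal(0, 1, 40), index=table.index)
        assoc = univariate_associations(table, y, task="regression")
        from scipy import stats as ss

        for col in table.columns:
            x = table[col] / table[col].std(ddof=0)
            lr = ss.linregress(x, y)
            assert assoc.loc[col, "coef"] == pytest.approx(lr.slope)
            assert assoc.loc[col, "p_value"] == pytest.approx(lr.pvalue, rel=1e-6)

    def test_logistic_pvalues_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        table = _random_table(rng, 80, 4)
        logits = 2 * (table.iloc[:, 0] - 0.5)
        y = pd.Series((rng.random(80) < 1 / (1 + np.exp(-logits))).astype(int), index=table.index)
        assoc = univariate_associations(table, y.map({0: "no", 1: "yes"}), task="binary")
        for col in table.columns:
            x = sm.add_constant(table[col] / table[col].std(ddof=0))
            fit = sm.Logit(y, x).fit(disp=0)
            assert assoc.loc[col, "coef"] == pytest.approx(fit.params.iloc[1], rel=1e-4)
            assert assoc.loc[col, "p_value"] == pytest.approx(fit.pvalues.iloc[1], rel=1e-3)


class TestClassWeights:
    def test_imbalanced_hand_example(self):
        labels = pd.Series(["A"] * 80 + ["B"] * 20)
        w = mv.class_weights(labels)
        assert w[labels == "A"].unique() == pytest.approx([0.625])
        assert w[labels == "B"].unique() == pytest.approx([2.5])
        assert w.mean() == pytest.approx(1.0)

    def test_balanced_classes_unit_weights(self):
        w = mv.class_weights(pd.Series(["x", "y"] * 10))
        np.testing.assert_allclose(w, 1.0)

    def test_three_class_ratios_and_total(self):
        labels = pd.Series(["a"] * 50 + ["b"] * 30 + ["c"] * 20)
        w = mv.class_weights(labels)
        ra = w[labels == "a"].iloc[0]
        rb = w[labels == "b"].iloc[0]
        rc = w[labels == "c"].iloc[0]
        assert rb / ra == pytest.approx((1 / 0.3) / (1 / 0.5))
        assert rc / ra == pytest.approx((1 / 0.2) / (1 / 0.5))
        assert w.sum() == pytest.approx(100.0)  # mean-1 normalization

    def test_single_class_error(self):
        with pytest.raises(ConfigurationError):
            mv.class_weights(pd.Series(["only"] * 5))


class TestExtractGenes:
    def test_bonferroni_rule(self):
        rng = np.random.default_rng(8)
        d = mv.StudyDesign(n_subjects=80, samples_per_subject=(1, 1), seed=8)
        sig = mv.SignalSpec(
            blocks=[mv.Block(f"b{i}", 5, 0.95) for i in range(4)],
            effects=[mv.Effect("b0", "sex", 3.0)],
        )
        meta = mv.generate_metadata(d)
        genes, truth = mv.generate_gene_abundances(d, sig, meta)
        importances = pd.Series({"b0": 0.9, "b1": 0.05, "b2": 0.05, "b3": 0.0})
        sub = mv.extract_genes_from_top_cags(
            importances, truth, genes, meta["sex"], task="binary", n_cags=2
        )
        candidates = set(truth.groups()["b0"]) | set(truth.groups()["b1"])
        assert set(sub.columns).issubset(candidates)
        # the driven block's genes should dominate the surviving set
        assert len(set(sub.columns) & set(truth.groups()["b0"])) >= 3
        # surviving genes really beat alpha / n_candidates
        assoc = univariate_associations(genes[sorted(candidates)], meta["sex"], task="binary")
        cut = 0.05 / len(candidates)
        assert set(sub.columns) == set(assoc.index[assoc.p_value < cut])

    def test_no_survivor_returns_empty(self):
        d = mv.StudyDesign(n_subjects=30, samples_per_subject=(1, 1), seed=9)
        sig = mv.SignalSpec(blocks=[mv.Block("b0", 4), mv.Block("b1", 4)], null=True)
        meta = mv.generate_metadata(d)
        genes, truth = mv.generate_gene_abundances(d, sig, meta)
        sub = mv.extract_genes_from_top_cags(
            pd.Series({"b0": 1.0, "b1": 0.5}), truth, genes, meta["sex"],
            task="binary", n_cags=2, alpha=1e-6,
        )
        assert sub.shape[1] == 0
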