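"""TOO pipeline: TMM, FPKM, gini selection, classifier, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from oncoprofile import simulate, too
from oncoprofile.too import ExpressionCohort


def tmm_oracle(counts: pd.DataFrame, sample: str, reference: str) -> float:
    """Literal-from-definition TMM factor, written as plain loops.

    Doubly trimmed (30% M, 5% A each side by rank) weighted mean of
    per-gene log2 ratios with asymptotic-binomial precision weights.
    """
    obs = counts[sample].to_numpy(dtype=float)
    ref = counts[reference].to_numpy(dtype=float)
    n_obs, n_ref = obs.sum(), ref.sum()
    m_vals, a_vals, w_vals = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m_vals.append(np.log2((o / n_obs) / (r / n_ref)))
            a_vals.append(0.5 * np.log2((o / n_obs) * (r / n_ref)))
            w_vals.append((n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r))
    m = np.array(m_vals)
    a = np.array(a_vals)
    w = np.array(w_vals)
    if np.allclose(m, m[0]):
        return 1.0
    n = len(m)
    m_rank = rankdata(m)
    a_rank = rankdata(a)
    num = den = 0.0
    for i in range(n):
        if not (n * 0.30 < m_rank[i] <= n * 0.70):
            continue
        if not (n * 0.05 < a_rank[i] <= n * 0.95):
            continue
        num += m[i] / w[i]
        den += 1.0 / w[i]
    if den == 0:
        return 1.0
    return float(2.0 ** (num / den))


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 30], "B": [10, 20, 30]},
                              index=["g1", "g2", "g3"])
        assert np.allclose(too.tmm_factors(counts), 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(100, size=50)
        counts = pd.DataFrame({"A": a, "B": 2 * a},
                              index=[f"g{i}" for i in range(50)])
        assert np.allclose(too.tmm_factors(counts), 1.0)

    def test_matches_from_definition_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            counts = pd.DataFrame(
                rng.poisson(rng.uniform(5, 500, size=(50, 1)), size=(50, 4)),
                index=[f"g{i}" for i in range(50)],
                columns=list("ABCD"),
            )
            lib = counts.sum(axis=0)
            q75 = counts.div(lib, axis=1).quantile(0.75)
            ref = (q75 - q75.mean()).abs().idxmin()
            factors = too.tmm_factors(counts)
            raw = {s: 1.0 if s == ref else tmm_oracle(counts, s, ref)
                   for s in counts.columns}
            raw = pd.Series(raw)[counts.columns]
            expected = raw / np.exp(np.log(raw).mean())
            assert np.allclose(factors, expected, atol=1e-8), trial

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(50, size=(100, 6)),
                              index=[f"g{i}" for i in range(100)])
        f = too.tmm_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_scaling_one_library_leaves_factors_invariant(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(80, size=(60, 3)),
                              index=[f"g{i}" for i in range(60)],
                              columns=list("XYZ"))
        scaled = counts.copy()
        scaled["Y"] = scaled["Y"] * 7
        # M and A values are depth-invariant; only the precision weights
        # move, so the factors agree closely but not to machine precision.
        assert np.allclose(too.tmm_factors(counts), too.tmm_factors(scaled),
                           atol=0.02)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"A": [1, 2], "B": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="all-zero"):
            too.tmm_factors(counts)


class TestFpkm:
    def test_definition(self):
        counts = pd.DataFrame({"S": [10, 0]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 500], index=["g1", "g2"])
        libs = pd.Series({"S": 1e6})
        out = too.fpkm(counts, lengths, libs)
        assert out.loc["g1", "S"] == pytest.approx(10.0)
        assert out.loc["g2", "S"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"S": [10, 20]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 2000], index=["g1", "g2"])
        one = too.fpkm(counts, lengths, pd.Series({"S": 1e6}))
        two = too.fpkm(counts, lengths, pd.Series({"S": 2e6}))
        assert np.allclose(two, one / 2)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"S": [10]}, index=["g1"])
        with pytest.raises(ValueError):
            too.fpkm(counts, pd.Series([100], index=["g1"]), pd.Series({"S": 0}))


class TestGiniScore:
    def test_perfect_two_class_separator_scores_one(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        y = np.r_[["A"] * 50, ["B"] * 50]
        assert too.gini_gene_score(x, y) == pytest.approx(1.0)

    def test_constant_gene_scores_zero(self):
        assert too.gini_gene_score(np.ones(40), ["A", "B"] * 20) == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            too.gini_gene_score(np.arange(10), ["A"] * 10)

    def test_perfect_one_vs_rest_separator_scores_one_in_multiclass(self):
        rng = np.random.default_rng(4)
        y = np.repeat(["A", "B", "C", "D", "E"], 20)
        x = rng.normal(0, 0.1, 100)
        x[y == "C"] += 10
        assert too.gini_gene_score(x, y) == pytest.approx(1.0)

    @pytest.mark.parametrize("transform", [
        lambda x: np.exp(x), lambda x: 2 * x + 3, lambda x: rankdata(x),
    ])
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        y = rng.choice(["A", "B", "C"], size=60)
        assert too.gini_gene_score(transform(x), y) == pytest.approx(
            too.gini_gene_score(x, y)
        )

    def test_permuted_labels_fall_inside_null(self):
        rng = np.random.default_rng(6)
        y = np.repeat(["A", "B"], 100)
        x = rng.normal(size=200)
        x[y == "A"] += 3.0
        perm = rng.permutation(y)
        score = too.gini_gene_score(x, perm)
        null = [too.gini_gene_score(x, rng.permutation(y)) for _ in range(100)]
        assert score < np.percentile(null, 95)
        # and far below the true-label score
        assert score < 0.5 * too.gini_gene_score(x, y)


class TestSelectGeneSet:
    def test_threshold_is_inclusive(self):
        scores = pd.Series({"a": 0.5, "b": 0.3, "c": 0.29})
        assert too.select_gene_set(scores) == ["a", "b"]

    def test_max_genes_truncates(self):
        scores = pd.Series({"a": 0.5, "b": 0.3, "c": 0.29})
        assert too.select_gene_set(scores, max_genes=1) == ["a"]

    def test_fallback_when_nothing_clears_threshold(self):
        scores = pd.Series({"a": 0.2, "b": 0.1})
        with pytest.warns(UserWarning, match="falling back"):
            assert too.select_gene_set(scores, max_genes=1) == ["a"]

    def test_recovers_informative_genes(self):
        cohort, truth = simulate.gen_expression_cohort(
            n_classes=5, n_per_class=50, n_genes=150, n_informative=30,
            effect_log2fc=3.0, seed=9,
        )
        cohort.normalize()
        scores = pd.Series({
            g: too.gini_gene_score(cohort.fpkm.loc[g], cohort.labels)
            for g in cohort.counts.index
        })
        selected = set(too.select_gene_set(scores))
        informative = set(truth.informative_genes)
        assert len(selected & informative) >= 0.8 * len(informative)


class TestClassifier:
    def test_single_informative_gene_two_classes(self):
        rng = np.random.default_rng(7)
        n = 40
        labels = pd.Series(np.repeat(["A", "B"], n // 2),
                           index=[f"S{i}" for i in range(n)])
        counts = pd.DataFrame(
            rng.poisson(50, size=(5, n)),
            index=[f"g{i}" for i in range(5)],
            columns=labels.index,
        )
        counts.iloc[0, : n // 2] += 500  # clean separation on g0
        cohort = ExpressionCohort(
            counts=counts, gene_lengths=pd.Series(1000, index=counts.index),
            labels=labels,
        ).normalize()
        model = too.train_too(cohort, ["g0"], seed=0)
        report = too.evaluate_too(too.predict_too(model, cohort), labels)
        assert report["top1_accuracy"] == 1.0

    def test_class_with_single_sample_rejected(self):
        labels = pd.Series(["A", "A", "B"], index=["S0", "S1", "S2"])
        counts = pd.DataFrame(np.ones((3, 3), dtype=int) * 10,
                              index=["g0", "g1", "g2"], columns=labels.index)
        cohort = ExpressionCohort(
            counts=counts, gene_lengths=pd.Series(100, index=counts.index),
            labels=labels,
        )
        with pytest.raises(ValueError, match="< 2 samples"):
            too.train_too(cohort, ["g0"])

    def test_degenerate_one_class_model_predicts_it_with_certainty(self):
        labels = pd.Series(["A", "A", "A"], index=["S0", "S1", "S2"])
        counts = pd.DataFrame(np.ones((2, 3), dtype=int) * 10,
                              index=["g0", "g1"], columns=labels.index)
        cohort = ExpressionCohort(
            counts=counts, gene_lengths=pd.Series(100, index=counts.index),
            labels=labels,
        )
        model = too.train_too(cohort, ["g0"])
        preds = too.predict_too(model, cohort)
        assert all(p.top1 == ("A", 1.0) for p in preds)

    def test_probabilities_sum_to_one(self, expression_cohort):
        cohort, _ = expression_cohort
        model = too.train_too(cohort, list(cohort.counts.index[:20]), seed=0)
        preds = too.predict_too(model, cohort)
        for p in preds[:10]:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert p.top1[1] >= p.top2[1]

    def test_top2_accuracy_dominates_top1(self, expression_cohort):
        cohort, _ = expression_cohort
        tr, te = train_test_split(cohort.counts.columns, test_size=0.5,
                                  random_state=0, stratify=cohort.labels)
        trc = ExpressionCohort(cohort.counts[tr], cohort.gene_lengths,
                               cohort.labels[tr]).normalize()
        tec = ExpressionCohort(cohort.counts[te], cohort.gene_lengths,
                               cohort.labels[te]).normalize()
        model = too.train_too(trc, list(cohort.counts.index[:40]), seed=0)
        report = too.evaluate_too(too.predict_too(model, tec), tec.labels)
        assert report["top2_accuracy"] >= report["top1_accuracy"]


class TestEvaluate:
    def test_all_correct(self):
        preds = [too.TooPrediction(("A", 0.9), ("B", 0.1),
                                   pd.Series({"A": 0.9, "B": 0.1}))]
        assert too.evaluate_too(preds, ["A"])["top1_accuracy"] == 1.0

    def test_half_correct(self):
        p = pd.Series({"A": 0.6, "B": 0.3, "C": 0.1})
        preds = [
            too.TooPrediction(("A", 0.6), ("B", 0.3), p),
            too.TooPrediction(("C", 0.5), ("A", 0.4),
                              pd.Series({"A": 0.4, "B": 0.1, "C": 0.5})),
        ]
        report = too.evaluate_too(preds, ["A", "B"])
        assert report["top1_accuracy"] == 0.5

    def test_confusion_rows_sum_to_class_counts(self, expression_cohort):
        cohort, _ = expression_cohort
        model = too.train_too(cohort, list(cohort.counts.index[:40]), seed=0)
        report = too.evaluate_too(too.predict_too(model, cohort), cohort.labels)
        counts = cohort.labels.value_counts()
        for cls in counts.index:
            assert report["confusion"].loc[cls].sum() == counts[cls]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            too.evaluate_too([], ["A"])
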