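import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from negsel import (
    ConfusionCounts,
    PerceptronConfig,
    binary_metrics,
    degree_pair_feature,
    experiment_grid,
    inflation_test,
    mcc,
    monte_carlo_cv,
    signal_planted_graph,
    topological_feature,
    train_perceptron,
)
from negsel.evaluation import FeatureFunction

counts = st.integers(min_value=0, max_value=10_000)


class TestMCC:
    def test_perfect_classification(self):
        assert mcc(ConfusionCounts(tp=10, tn=10, fp=0, fn=0)) == 1.0

    def test_perfect_misclassification(self):
        assert mcc(ConfusionCounts(tp=0, tn=0, fp=10, fn=10)) == -1.0

    def test_chance_level(self):
        assert mcc(ConfusionCounts(tp=5, tn=5, fp=5, fn=5)) == 0.0

    def test_hand_computed_value(self):
        # (45*35 - 15*5) / sqrt(60*50*50*40)
        expected = (45 * 35 - 15 * 5) / np.sqrt(60 * 50 * 50 * 40)
        assert mcc(ConfusionCounts(tp=45, tn=35, fp=15, fn=5)) == pytest.approx(expected)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=0, tn=5, fp=0, fn=5)) == 0.0

    @settings(deadline=None, max_examples=200)
    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    def test_bounded_and_class_swap_symmetric(self, tp, tn, fp, fn):
        a = mcc(ConfusionCounts(tp, tn, fp, fn))
        b = mcc(ConfusionCounts(tn, tp, fn, fp))
        assert -1.0 <= a <= 1.0
        assert a == pytest.approx(b)

    @settings(deadline=None, max_examples=50)
    @given(tp=counts, tn=counts, fp=counts, fn=counts)
    def test_matches_sklearn(self, tp, tn, fp, fn):
        labels = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        preds = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        if not labels:
            return
        ours = mcc(ConfusionCounts(tp, tn, fp, fn))
        assert ours == pytest.approx(matthews_corrcoef(labels, preds), abs=1e-12)


class TestBinaryMetrics:
    def test_perfect_separation(self):
        m = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m["auroc"] == 1.0 and m["mcc"] == 1.0 and m["f1"] == 1.0

    def test_random_scores_auroc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(binary_metrics(scores, labels)["auroc"] - 0.5) < 0.03

    def test_auroc_equals_pairwise_concordance(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.2])
        labels = np.array([0, 0, 1, 1, 1, 0])
        conc = ties = total = 0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                total += 1
                conc += sp > sn
                ties += sp == sn
        expected = (conc + 0.5 * ties) / total
        assert binary_metrics(scores, labels)["auroc"] == pytest.approx(expected)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            binary_metrics([0.5, 0.6], [1, 1])


class TestPerceptron:
    def test_separable_blobs_perfect_training_mcc(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(3, 0.3, (50, 2)), rng.normal(-3, 0.3, (50, 2))])
        y = np.concatenate([np.ones(50), np.zeros(50)])
        model = train_perceptron(X, y, seed=0)
        m = binary_metrics(model.predict_proba(X), y)
        assert m["mcc"] == 1.0

    def test_shuffled_labels_chance_mcc(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(400, 4))
        y = rng.integers(0, 2, 400)
        model = train_perceptron(X[:300], y[:300], seed=0)
        m = binary_metrics(model.predict_proba(X[300:]), y[300:])
        assert abs(m["mcc"]) < 0.25

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(60, 3)), rng.integers(0, 2, 60)
        a = train_perceptron(X, y, seed=9)
        b = train_perceptron(X, y, seed=9)
        assert np.array_equal(a.weights, b.weights) and a.bias == b.bias

    def test_nonfinite_features_error(self):
        with pytest.raises(ValueError, match="non-finite"):
            train_perceptron(np.array([[1.0], [np.nan]]), [0, 1])

    def test_standardization_fitted_on_train(self):
        rng = np.random.default_rng(4)
        X = rng.normal(100, 5, size=(80, 2))
        y = rng.integers(0, 2, 80)
        model = train_perceptron(X, y, standardize=True, seed=0)
        assert model.mean is not None
        assert np.allclose(model.mean, X.mean(axis=0))


@pytest.fixture(scope="module")
def planted():
    return signal_planted_graph(n_nodes=100, p_in=0.3, p_out=0.01, seed=5)


class TestMonteCarloCV:
    def test_planted_signal_recovered_with_either_sampler(self, planted):
        g, pos = planted
        for sampler in ("uns", "dans"):
            res = monte_carlo_cv(
                g, pos, topological_feature("jaccard"),
                train_sampler=sampler, eval_sampler=sampler,
                replicates=4, seed=0,
            )
            assert res.per_replicate.mcc.mean() > 0.3

    def test_constant_feature_gives_chance_mcc(self, planted):
        g, pos = planted
        const = FeatureFunction(
            lambda graph, pairs: np.ones((len(np.atleast_2d(pairs)), 2)), "constant"
        )
        res = monte_carlo_cv(g, pos, const, replicates=4, seed=1)
        assert abs(res.per_replicate.mcc.mean()) < 0.1

    def test_replicate_count_contract(self, planted):
        g, pos = planted
        res = monte_carlo_cv(g, pos, degree_pair_feature(), replicates=10, seed=2)
        assert len(res.per_replicate) == 10
        assert set(res.per_replicate.replicate) == set(range(10))

    def test_too_few_positives_errors(self, planted):
        g, pos = planted
        with pytest.raises(ValueError, match="at least 20"):
            monte_carlo_cv(g, pos[:5], degree_pair_feature(), seed=0)


class TestExperimentGrid:
    def test_grid_shape_contract(self, planted):
        g, pos = planted
        res = experiment_grid(g, pos, [degree_pair_feature()], replicates=10, seed=3)
        assert len(res.per_replicate) == 40  # 2 x 2 x 1 x 10
        long = res.to_long()
        assert set(long.metric) == {"mcc", "auroc", "auprc", "f1"}

    def test_inflation_on_hub_graph(self, hub_graph):
        pos = hub_graph._edges_of_type("sli")
        res = experiment_grid(g=hub_graph, positives=pos,
                              feature_fns=[degree_pair_feature()], replicates=6, seed=4)
        for train_sampler in ("uns", "dans"):
            diff, p = inflation_test(res, "degree_pair", train_sampler)
            assert diff > 0 and p < 0.05

    def test_paired_splits_share_positives(self, planted):
        # identical split seeds mean grid and single-condition runs pair up
        g, pos = planted
        grid_res = experiment_grid(g, pos, [degree_pair_feature()], replicates=3, seed=7)
        single = monte_carlo_cv(
            g, pos, degree_pair_feature(), "uns", "uns", replicates=3, seed=7
        )
        sel = grid_res.per_replicate.query("train_sampler=='uns' and eval_sampler=='uns'")
        assert np.allclose(
            sel.sort_values("replicate").mcc.to_numpy(),
            single.per_replicate.sort_values("replicate").mcc.to_numpy(),
        )

    def test_summary_mean_std_columns(self, planted):
        g, pos = planted
        res = experiment_grid(g, pos, [degree_pair_feature()], replicates=3, seed=8)
        s = res.summary()
        assert {"mcc_mean", "mcc_std", "auroc_mean"} <= set(s.columns)
        assert len(s) == 4


def test_plot_metric_bars_writes_file(tmp_path, planted):
    from negsel import plot_metric_bars

    g, pos = planted
    res = experiment_grid(g, pos, [degree_pair_feature()], replicates=2, seed=9)
    out = tmp_path / "bars.png"
    plot_metric_bars(res, "mcc", path=out)
    assert out.stat().st_size > 0
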