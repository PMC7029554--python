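import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sctwiner import (
    auprc,
    gaussian_nb,
    misclassifications,
    mse,
    nb_benchmark,
    regulation_direction,
    run_protocol,
    stratified_split,
)
from sctwiner.glm import PenaltyConfig

from oracles import auprc_brute, gaussian_nb_brute


class TestStratifiedSplit:
    def test_exact_stratification(self):
        y = np.array([1] * 100 + [0] * 100)
        tr, te = stratified_split(y, 0.75, seed=0)
        assert len(tr) == 150 and len(te) == 50
        assert y[tr].sum() == 75 and y[te].sum() == 25

    def test_partition_property(self):
        y = np.array([1] * 37 + [0] * 63)
        tr, te = stratified_split(y, 0.6, seed=3)
        assert sorted(np.concatenate([tr, te])) == list(range(100))
        assert len(set(tr) & set(te)) == 0

    def test_same_seed_identical(self):
        y = np.array([0, 1] * 30)
        a = stratified_split(y, 0.75, seed=42)
        b = stratified_split(y, 0.75, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_train_proportions_track_overall(self):
        y = np.array([1] * 40 + [0] * 60)
        for seed in range(100):
            tr, _ = stratified_split(y, 0.75, seed)
            prop = y[tr].mean()
            assert abs(prop - 0.4) <= 1 / 40

    def test_class_too_small_errors(self):
        y = np.array([1, 0, 0, 0])
        with pytest.raises(ValueError, match="cannot appear"):
            stratified_split(y, 0.75, 0)


class TestMetrics:
    def test_mse_values(self):
        assert mse([1.0, 0.0], [1, 0]) == 0.0
        assert mse([0.5, 0.5], [1, 0]) == 0.25
        assert mse([0.9, 0.2], [1, 0]) == pytest.approx(0.025)

    def test_mse_empty_errors(self):
        with pytest.raises(ValueError):
            mse([], [])

    def test_auprc_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_auprc_perfectly_wrong_matches_step_rule(self):
        scores, labels = np.array([0.4, 0.6]), np.array([1, 0])
        assert auprc(scores, labels) == pytest.approx(
            auprc_brute(scores, labels), abs=1e-12
        )

    def test_auprc_tie_fixture_matches_enumeration(self):
        scores = np.array([0.9, 0.7, 0.7, 0.4, 0.3, 0.1])
        labels = np.array([1, 1, 0, 1, 0, 0])
        assert auprc(scores, labels) == pytest.approx(
            auprc_brute(scores, labels), abs=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_auprc_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        scores = np.round(rng.random(n), 1)  # induce ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert auprc(scores, labels) == pytest.approx(
            auprc_brute(scores, labels), abs=1e-10
        )

    def test_auprc_single_class_errors(self):
        with pytest.raises(ValueError):
            auprc([0.4, 0.5], [1, 1])

    def test_misclassification_ge_convention(self):
        # p = 0.5 counts as a positive call
        assert misclassifications([0.5] * 4, [0, 0, 0, 0]) == 4
        assert misclassifications([0.5] * 4, [1, 1, 1, 1]) == 0
        assert misclassifications([0.9, 0.2, 0.4], [1, 0, 1]) == 1


class TestRegulationDirection:
    def test_directions(self):
        X = np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0], [3.0, 1.0, 2.0], [3.0, 1.0, 2.0]])
        y = np.array([1, 1, 0, 0])
        d = regulation_direction(X, y, ["a", "b", "c"], ["a", "b", "c"])
        assert d == {"a": "down", "b": "up", "c": "unchanged"}

    def test_planted_genes_up_in_neoplastic(self, medium_dataset):
        from sctwiner import make_labels, T_CORE, T_PERIPHERY, N_PERIPHERY
        from sctwiner.containers import align_expression

        (expr, ann, truth), design = medium_dataset
        labels, _ = make_labels(ann, [T_CORE, T_PERIPHERY], [N_PERIPHERY])
        em = align_expression(expr, labels)
        d = regulation_direction(
            em.values, labels.values, truth.discriminative_genes, list(em.gene_ids)
        )
        assert all(v == "up" for v in d.values())


class TestGaussianNB:
    def test_symmetric_midpoint_posterior(self):
        train_x = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.2], [0.8]])
        train_y = np.array([0, 0, 0, 1, 1, 1])
        p = gaussian_nb(train_x, train_y, np.array([[0.0]]))
        assert p[0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_closed_form_bayes(self):
        rng = np.random.default_rng(12)
        train_x = rng.standard_normal((6, 1)) + np.array([[0], [0], [0], [2], [2], [2]])
        train_y = np.array([0, 0, 0, 1, 1, 1])
        test_x = rng.standard_normal((5, 1))
        np.testing.assert_allclose(
            gaussian_nb(train_x, train_y, test_x),
            gaussian_nb_brute(train_x, train_y, test_x),
            atol=1e-12,
        )

    def test_constant_feature_does_not_flip_predictions(self):
        rng = np.random.default_rng(5)
        train_x = np.vstack([rng.normal(-1, 1, (20, 2)), rng.normal(1, 1, (20, 2))])
        train_y = np.array([0] * 20 + [1] * 20)
        test_x = rng.standard_normal((10, 2))
        p1 = gaussian_nb(train_x, train_y, test_x)
        const = np.full((40, 1), 3.14)
        p2 = gaussian_nb(
            np.hstack([train_x, const]), train_y,
            np.hstack([test_x, np.full((10, 1), 3.14)]),
        )
        np.testing.assert_array_equal(p1 >= 0.5, p2 >= 0.5)

    def test_single_class_training_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            gaussian_nb(np.ones((3, 1)), np.zeros(3), np.ones((1, 1)))


@pytest.fixture(scope="module")
def protocol_data(request):
    rng = np.random.default_rng(77)
    n, p = 200, 30
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:4] = 2.0
    from scipy.special import expit

    y = (rng.random(n) < expit(X @ beta)).astype(int)
    y[:2] = [0, 1]
    return X, y


class TestRunProtocol:
    def test_single_run_frequencies_binary(self, protocol_data):
        X, y = protocol_data
        stab = run_protocol(X, y, PenaltyConfig(0.05, 0.5), n_runs=1, seed=0)
        assert set(np.unique(stab.selection_frequency)) <= {0.0, 1.0}
        row = stab.metrics.iloc[0]
        for k in ("mse_train", "mse_test", "auc_train", "auc_test", "n_selected"):
            assert stab.median_summary[k] == row[k]

    def test_protocol_determinism(self, protocol_data):
        X, y = protocol_data
        a = run_protocol(X, y, PenaltyConfig(0.05, 0.5), n_runs=5, seed=9)
        b = run_protocol(X, y, PenaltyConfig(0.05, 0.5), n_runs=5, seed=9)
        np.testing.assert_array_equal(a.selection_frequency, b.selection_frequency)
        assert a.metrics.equals(b.metrics)

    def test_planted_genes_dominate_selection(self, protocol_data):
        X, y = protocol_data
        stab = run_protocol(X, y, PenaltyConfig(0.15, 0.5), n_runs=30, seed=1)
        freq = stab.selection_frequency
        assert freq.iloc[:4].min() > freq.iloc[4:].max()

    def test_consensus_monotone_in_threshold(self, protocol_data):
        X, y = protocol_data
        stab = run_protocol(X, y, PenaltyConfig(0.02, 0.5), n_runs=20, seed=2)
        sizes = [len(stab.consensus_at(t)) for t in (0.1, 0.5, 0.75, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_median_n_selected_consistency(self, protocol_data):
        X, y = protocol_data
        stab = run_protocol(X, y, PenaltyConfig(0.05, 0.5), n_runs=11, seed=3)
        assert stab.median_summary["n_selected"] == stab.metrics.n_selected.median()

    def test_consensus_overlap_across_master_seeds(self, protocol_data):
        X, y = protocol_data
        a = run_protocol(X, y, PenaltyConfig(0.05, 0.5), n_runs=30, seed=100)
        b = run_protocol(X, y, PenaltyConfig(0.05, 0.5), n_runs=30, seed=200)
        sa, sb = set(a.consensus.gene_ids), set(b.consensus.gene_ids)
        assert sa and sb
        jaccard = len(sa & sb) / len(sa | sb)
        assert jaccard > 0.8


class TestNBBenchmark:
    def test_perfectly_separated_classes(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-6, 0.5, (30, 3)), rng.normal(6, 0.5, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        table = nb_benchmark(X, y, PenaltyConfig(0.01, 0.5), n_runs=5, seed=0)
        assert (table.auc_test == 1.0).all()
        assert (table.miscl_test == 0).all()

    def test_signal_genes_beat_random_genes(self, protocol_data):
        X, y = protocol_data
        signal = nb_benchmark(
            X, y, PenaltyConfig(0.02, 0.5), n_runs=25, seed=4,
            fixed_genes=["x0", "x1", "x2", "x3"],
        )
        noise = nb_benchmark(
            X, y, PenaltyConfig(0.02, 0.5), n_runs=25, seed=4,
            fixed_genes=["x10", "x11", "x12", "x13"],
        )
        assert signal.auc_test.median() > noise.auc_test.median()

    def test_metrics_schema_invariants(self, protocol_data):
        X, y = protocol_data
        table = nb_benchmark(X, y, PenaltyConfig(0.05, 0.5), n_runs=4, seed=5)
        n_test = len(y) - int(round(0.75 * (y == 1).sum())) - int(round(0.75 * (y == 0).sum()))
        assert len(table) == 4
        assert (table.auc_test.between(0, 1)).all()
        assert (table.miscl_test <= n_test).all()
        assert (table.n_selected > 0).all()
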