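"""Fold splitting, ROC/AUC and the two evaluation protocols."""

import numpy as np
import pytest

import ksimc
from ksimc.evaluation import roc_points, ten_fold_split
from oracles import mann_whitney_auc


def make_pairs(n):
    return {(f"K{i}", f"S{i}") for i in range(n)}


class TestTenFoldSplit:
    def test_exact_division(self):
        fa = ten_fold_split(make_pairs(20), seed=0)
        sizes = [len(f) for f in fa.folds()]
        assert sizes == [2] * 10

    def test_remainder_distribution(self):
        fa = ten_fold_split(make_pairs(23), seed=0)
        sizes = sorted((len(f) for f in fa.folds()), reverse=True)
        assert sizes == [3, 3, 3] + [2] * 7

    def test_deterministic_and_seed_sensitive(self):
        pairs = make_pairs(37)
        assert ten_fold_split(pairs, seed=5).fold_of_pair == ten_fold_split(pairs, seed=5).fold_of_pair
        assert ten_fold_split(pairs, seed=5).fold_of_pair != ten_fold_split(pairs, seed=6).fold_of_pair

    def test_partition_properties(self):
        pairs = make_pairs(41)
        folds = ten_fold_split(pairs, seed=1).folds()
        assert frozenset().union(*folds) == frozenset(pairs)
        for i in range(10):
            for j in range(i + 1, 10):
                assert not folds[i] & folds[j]

    def test_too_few_positives(self):
        with pytest.raises(ValueError):
            ten_fold_split(make_pairs(9), seed=0)

    def test_independent_of_input_order(self):
        pairs = sorted(make_pairs(25))
        assert ten_fold_split(pairs, 3).fold_of_pair == ten_fold_split(pairs[::-1], 3).fold_of_pair


class TestRocPoints:
    def test_perfect_separation(self):
        assert roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == 1.0

    def test_anti_perfect(self):
        assert roc_points([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]).auc == 0.0

    def test_curve_endpoints_and_monotonicity(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        roc = roc_points(scores, labels)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_auc_equals_mann_whitney_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            # quantised scores force plenty of ties
            scores = rng.integers(0, 6, n) / 5.0
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_points(scores, labels).auc == pytest.approx(
                mann_whitney_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores = rng.random(60)
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert roc_points(scores, labels).auc == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([0.1, 0.2], [1, 1])


class TestCrossValidate:
    def test_planted_structure_recovered(self, default_cv):
        assert default_cv.pooled.auc > 0.9

    def test_folds_partition_positive_set(self, default_cv, default_instance):
        folds = default_cv.assignment.folds()
        assert frozenset().union(*folds) == default_instance.observed_interactions

    def test_destroyed_structure_scores_at_chance(self, null_cv):
        assert 0.4 <= null_cv.pooled.auc <= 0.6

    def test_deterministic_for_fixed_seed(self, default_instance, default_sims, default_cv):
        sim_kin, sim_sub = default_sims
        again = ksimc.cross_validate(
            default_instance.kinases,
            default_instance.substrates,
            default_instance.interaction_list(),
            ksimc.RunConfig(),
            sim_kin=sim_kin,
            sim_sub=sim_sub,
        )
        assert again.pooled.auc == default_cv.pooled.auc
        assert again.fold_aucs == default_cv.fold_aucs

    def test_no_leakage_in_any_fold(self, default_instance, default_sims):
        """Held-out positives must be absent from every fold's training
        matrix before the adjustment stage runs."""
        sim_kin, sim_sub = default_sims
        il = default_instance.interaction_list()
        kpos = {k: i for i, k in enumerate(il.kinase_ids)}
        spos = {s: j for j, s in enumerate(il.substrate_ids)}
        seen = []

        def inspect(fold, train_matrix, test_pairs, train_pairs):
            assert not test_pairs & train_pairs
            for k, s in test_pairs:
                assert train_matrix[kpos[k], spos[s]] == 0
            for k, s in train_pairs:
                assert train_matrix[kpos[k], spos[s]] == 1
            seen.append(frozenset(test_pairs))

        cfg = ksimc.RunConfig(max_iter=5)  # instrumentation run; scores not assessed
        ksimc.cross_validate(
            default_instance.kinases, default_instance.substrates, il, cfg,
            sim_kin=sim_kin, sim_sub=sim_sub, inspect=inspect,
        )
        assert len(seen) == 10
        assert frozenset().union(*seen) == il.pairs


@pytest.fixture(scope="module")
def busiest_kinase(default_instance):
    counts = {}
    for k, _ in default_instance.observed_interactions:
        counts[k] = counts.get(k, 0) + 1
    return max(sorted(counts), key=counts.get)


class TestDeNovo:
    def test_planted_kinase_recovered(self, default_instance, default_sims, busiest_kinase):
        sim_kin, sim_sub = default_sims
        roc = ksimc.de_novo_test(
            default_instance.kinases, default_instance.substrates,
            default_instance.interaction_list(), busiest_kinase, ksimc.RunConfig(),
            sim_kin=sim_kin, sim_sub=sim_sub,
        )
        assert roc.auc > 0.8

    def test_unstructured_kinase_in_null_band(self, default_instance, default_sims):
        """Replace one kinase's substrates with uniformly random ones: its
        de-novo AUC should sit in the wide chance band."""
        sim_kin, sim_sub = default_sims
        il = default_instance.interaction_list()
        kid = il.kinase_ids[0]
        others = frozenset(p for p in il.pairs if p[0] != kid)
        rng = np.random.default_rng(99)
        fake_subs = rng.choice(len(il.substrate_ids), size=6, replace=False)
        scrambled = others | {(kid, il.substrate_ids[j]) for j in fake_subs}
        roc = ksimc.de_novo_test(
            default_instance.kinases, default_instance.substrates,
            il.with_pairs(scrambled), kid, ksimc.RunConfig(),
            sim_kin=sim_kin, sim_sub=sim_sub,
        )
        assert 0.3 <= roc.auc <= 0.7

    def test_deletion_isolated_to_queried_kinase(self, default_instance, default_sims, busiest_kinase):
        sim_kin, sim_sub = default_sims
        il = default_instance.interaction_list()
        captured = {}

        def inspect(train_matrix, removed):
            captured["matrix"] = train_matrix
            captured["removed"] = removed

        ksimc.de_novo_test(
            default_instance.kinases, default_instance.substrates, il, busiest_kinase,
            ksimc.RunConfig(max_iter=5), sim_kin=sim_kin, sim_sub=sim_sub, inspect=inspect,
        )
        row = il.kinase_ids.index(busiest_kinase)
        full = ksimc.build_interaction_matrix(il).values
        assert not captured["matrix"][row].any()
        mask = np.ones(len(il.kinase_ids), dtype=bool)
        mask[row] = False
        assert np.array_equal(captured["matrix"][mask], full[mask])

    def test_kinase_without_substrate_rejected(self, default_instance, default_sims):
        sim_kin, sim_sub = default_sims
        il = default_instance.interaction_list()
        kid = il.kinase_ids[0]
        stripped = il.with_pairs(p for p in il.pairs if p[0] != kid)
        with pytest.raises(ValueError, match="no known substrate"):
            ksimc.de_novo_test(
                default_instance.kinases, default_instance.substrates, stripped, kid,
                ksimc.RunConfig(), sim_kin=sim_kin, sim_sub=sim_sub,
            )
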