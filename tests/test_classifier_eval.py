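import numpy as np
import pytest
from scipy.stats import rankdata

from smmda.classifier_eval import (
    CVConfig,
    GBTParams,
    compute_metrics,
    cross_validate,
    rank_candidates,
    sample_negatives,
    summarize_folds,
    train_classifier,
)
from smmda.autoencoder import AEConfig
from smmda.core_data import AssociationList, AssociationMatrix, build_adjacency
from smmda.errors import (
    CapacityError,
    DegenerateInputError,
    EntityLookupError,
)
from smmda.fusion import FusedFeatureMatrix, PairDataset


def mannwhitney_auc(labels, scores):
    """Rank-statistic oracle: U/(n+ * n-) with midranks for ties."""
    labels = np.asarray(labels)
    ranks = rankdata(scores)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def toy_dataset(n=40, seed=0, width=2, separable=True):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.random((n, width))
    if separable:
        X[:, 0] = y + 0.1 * rng.random(n)
    return PairDataset(
        features=X, labels=y.astype(np.int8),
        pair_ids=tuple((f"m{i}", f"d{i}") for i in range(n)),
        block_spec=(width, 0),
    )


class TestSampleNegatives:
    @staticmethod
    def _matrix():
        return build_adjacency(AssociationList.from_pairs([("m1", "d1"), ("m2", "d2")]))

    def test_exhaustive_when_n_equals_zero_cells(self):
        A = self._matrix()
        neg = sample_negatives(A, 2, seed=0)
        assert set(neg.pairs) == {("m1", "d2"), ("m2", "d1")}

    def test_zero_request(self):
        assert len(sample_negatives(self._matrix(), 0, seed=0)) == 0

    def test_deterministic_and_disjoint_from_positives(self):
        rng = np.random.default_rng(1)
        values = (rng.random((8, 10)) < 0.3).astype(np.int8)
        A = AssociationMatrix(values=values,
                              disease_index=tuple(f"d{i}" for i in range(8)),
                              mirna_index=tuple(f"m{j}" for j in range(10)))
        a = sample_negatives(A, 15, seed=7)
        b = sample_negatives(A, 15, seed=7)
        assert a.pairs == b.pairs
        assert len(set(a.pairs)) == 15
        positives = set(A.positive_pairs())
        assert not positives & set(a.pairs)

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            sample_negatives(self._matrix(), 3, seed=0)


class TestTrainClassifier:
    def test_separable_toy_perfect_training_auc(self):
        ds = toy_dataset()
        model = train_classifier(ds, GBTParams(n_trees=50))
        scores = model.predict_proba(ds.features)[:, 1]
        assert mannwhitney_auc(ds.labels, scores) == 1.0

    def test_single_class_rejected(self):
        ds = toy_dataset()
        one_class = PairDataset(features=ds.features,
                                labels=np.ones(len(ds), dtype=np.int8),
                                pair_ids=ds.pair_ids, block_spec=ds.block_spec)
        with pytest.raises(DegenerateInputError):
            train_classifier(one_class)

    def test_label_permutation_null_auc_near_half(self):
        """Labels independent of features: CV AUC must hover around 0.5."""
        rng = np.random.default_rng(42)
        n = 2000
        X = rng.random((n, 8))
        y = rng.integers(0, 2, size=n).astype(np.int8)
        y[:2] = [0, 1]
        ds = PairDataset(features=X, labels=y,
                         pair_ids=tuple((f"m{i}", f"d{i}") for i in range(n)),
                         block_spec=(8, 0))
        _, summary, _ = cross_validate(
            ds, CVConfig(use_autoencoder=False, gbt=GBTParams(n_trees=50)), seed=0)
        assert abs(summary["auc"]["mean"] - 0.5) < 0.05


class TestComputeMetrics:
    def test_perfect_separation(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.9, 0.9, 0.1, 0.1, 0.1]
        m = compute_metrics(y, s)
        assert (m.acc, m.sen, m.spec, m.prec, m.mcc, m.auc, m.aupr) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_counts(self):
        # TP=3 FN=2 TN=2 FP=1 at threshold 0.5
        y = [1, 1, 1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2]
        m = compute_metrics(y, s)
        assert (m.tp, m.tn, m.fp, m.fn) == (3, 2, 1, 2)
        assert m.acc == pytest.approx(0.625)
        assert m.sen == pytest.approx(0.6)
        assert m.spec == pytest.approx(2 / 3)
        assert m.prec == pytest.approx(0.75)
        assert m.mcc == pytest.approx(0.2582, abs=1e-4)

    def test_reversed_scores_invert_auc(self):
        y = [1, 1, 0, 0]
        assert compute_metrics(y, [0.1, 0.2, 0.8, 0.9]).auc == 0.0

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_metrics([1, 1], [0.5, 0.6])

    def test_mcc_zero_denominator_warns(self):
        with pytest.warns(UserWarning, match="MCC"):
            m = compute_metrics([1, 1, 0], [0.9, 0.8, 0.7])
        assert m.mcc == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_auc_equals_mannwhitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        s = rng.random(n)
        m = compute_metrics(y, s)
        assert m.auc == pytest.approx(mannwhitney_auc(y, s), abs=1e-9)


class TestCrossValidate:
    def test_fold_partition_contract(self):
        ds = toy_dataset(n=100, seed=3, separable=False)
        _, _, prov = cross_validate(
            ds, CVConfig(use_autoencoder=False, gbt=GBTParams(n_trees=10)), seed=1)
        test_sets = [set(r["test_indices"]) for r in prov]
        sizes = [len(t) for t in test_sets]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 100
        for i, a in enumerate(test_sets):
            for b in test_sets[i + 1:]:
                assert not a & b
        for r in prov:
            assert not set(r["train_indices"]) & set(r["test_indices"])

    def test_summary_matches_recomputation_from_scores(self):
        ds = toy_dataset(n=60, seed=4)
        folds, summary, prov = cross_validate(
            ds, CVConfig(use_autoencoder=False, gbt=GBTParams(n_trees=10)), seed=2)
        recomputed = [
            compute_metrics(r["test_labels"], r["test_scores"], fold=r["fold"])
            for r in prov
        ]
        assert summarize_folds(recomputed) == summary
        assert [f.as_dict() for f in folds] == [f.as_dict() for f in recomputed]

    def test_autoencoder_fit_on_training_folds_only(self):
        ds = toy_dataset(n=80, seed=5, width=16)
        cfg = CVConfig(folds=2, gbt=GBTParams(n_trees=5),
                       ae=AEConfig(layer_widths=(8, 4, 8), epochs=2, seed=0))
        _, _, prov = cross_validate(ds, cfg, seed=0)
        for r in prov:
            assert r["ae_fit_on"] == "train"
            assert "ae_final_loss" in r

    def test_k_below_two_rejected(self):
        from smmda.errors import DataValidationError

        with pytest.raises(DataValidationError):
            cross_validate(toy_dataset(), CVConfig(folds=1), seed=0)


class TestRankCandidates:
    @staticmethod
    def _setup():
        rng = np.random.default_rng(9)
        mirnas = tuple(f"m{i}" for i in range(6))
        diseases = ("d0", "d1")
        mv = np.clip((rng.random((6, 6)) + rng.random((6, 6)).T) / 2, 0, 1)
        dv = np.array([[1.0, 0.4], [0.4, 1.0]])
        MFM = FusedFeatureMatrix(values=mv, index=mirnas,
                                 source_map=np.full((6, 6), "GM", dtype="<U2"))
        DFM = FusedFeatureMatrix(values=dv, index=diseases,
                                 source_map=np.full((2, 2), "GD", dtype="<U2"))
        ds = toy_dataset(n=40, seed=10, width=8, separable=False)
        model = train_classifier(ds, GBTParams(n_trees=5))
        return model, MFM, DFM

    def test_exclusion_partition(self):
        model, MFM, DFM = self._setup()
        known = {"m0", "m3"}
        result = rank_candidates(model, "d0", MFM, DFM, known, top_k=10)
        assert len(result.ranked) + len(known) == len(MFM.index)
        assert not {m for m, _ in result.ranked} & known

    def test_all_known_yields_empty(self):
        model, MFM, DFM = self._setup()
        result = rank_candidates(model, "d0", MFM, DFM, set(MFM.index), top_k=10)
        assert result.ranked == ()

    def test_scores_descending_with_name_tiebreak(self):
        model, MFM, DFM = self._setup()
        result = rank_candidates(model, "d1", MFM, DFM, set(), top_k=6)
        scores = [s for _, s in result.ranked]
        assert scores == sorted(scores, reverse=True)
        for (ma, sa), (mb, sb) in zip(result.ranked, result.ranked[1:]):
            if sa == sb:
                assert ma < mb

    def test_unknown_disease_rejected(self):
        model, MFM, DFM = self._setup()
        with pytest.raises(EntityLookupError):
            rank_candidates(model, "nope", MFM, DFM, set())
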