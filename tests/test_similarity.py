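import numpy as np
import pytest

from smmda.core_data import AssociationList, AssociationMatrix, build_adjacency
from smmda.errors import DataValidationError, DegenerateInputError, InvalidDAGError
from smmda.similarity import (
    DiseaseDAG,
    SemanticConfig,
    SimilarityMatrix,
    functional_similarity,
    gip_bandwidth,
    gip_similarity,
    load_functional_similarity,
    semantic_profile,
    semantic_similarity,
    semantic_similarity_matrix,
)

from conftest import random_dag, semantic_oracle


def gip_bruteforce(profiles: np.ndarray, delta: float) -> np.ndarray:
    n = profiles.shape[0]
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp(-delta * np.sum((profiles[i] - profiles[j]) ** 2))
    return K


class TestGIP:
    def test_bandwidth_hand_values(self):
        assert gip_bandwidth(np.array([[1, 0], [0, 1]])) == pytest.approx(1.0)
        assert gip_bandwidth(np.array([[1, 1], [1, 1]])) == pytest.approx(0.5)
        # the non-reciprocal printed variant returns the mean squared norm
        assert gip_bandwidth(np.array([[1, 1], [1, 1]]), form="printed") == pytest.approx(2.0)

    def test_all_zero_profiles_degenerate(self):
        with pytest.raises(DegenerateInputError):
            gip_bandwidth(np.zeros((3, 4)))

    def test_identity_matrix_off_diagonal(self):
        A = build_adjacency(AssociationList.from_pairs([("m1", "d1"), ("m2", "d2")]))
        for axis in ("mirna", "disease"):
            K = gip_similarity(A, axis)
            assert K.values[0, 1] == pytest.approx(np.exp(-2.0), abs=1e-12)
            assert np.diag(K.values).tolist() == [1.0, 1.0]

    def test_identical_profiles_similarity_one(self):
        A = build_adjacency(
            AssociationList.from_pairs([("m1", "d1"), ("m2", "d1"), ("m3", "d2")])
        )
        K = gip_similarity(A, "mirna")
        i, j = K.pos("m1"), K.pos("m2")
        assert K.values[i, j] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        values = (rng.random((6, 8)) < 0.4).astype(np.int8)
        values[0, 0] = 1  # keep at least one interaction
        A = AssociationMatrix(
            values=values,
            disease_index=tuple(f"d{i}" for i in range(6)),
            mirna_index=tuple(f"m{j}" for j in range(8)),
        )
        for axis, profiles in (("mirna", values.T), ("disease", values)):
            K = gip_similarity(A, axis)
            delta = gip_bandwidth(profiles)
            expected = gip_bruteforce(profiles.astype(float), delta)
            np.fill_diagonal(expected, 1.0)
            assert np.allclose(K.values, expected, atol=1e-12)
            assert np.allclose(K.values, K.values.T, atol=1e-12)
            assert K.values.min() > 0 and K.values.max() <= 1


class TestSemantic:
    def test_single_node(self, half_delta):
        dag = DiseaseDAG(disease="a", nodes=frozenset({"a"}), edges=frozenset())
        p = semantic_profile(dag, half_delta)
        assert p.contributions == {"a": 1.0}
        assert p.dv == 1.0

    def test_chain_hand_values(self, chain_dag, half_delta):
        p = semantic_profile(chain_dag, half_delta)
        assert p.contributions == {"a": 1.0, "b": 0.5, "c": 0.25}
        assert p.dv == pytest.approx(1.75)

    def test_diamond_max_rule(self, half_delta):
        dag = DiseaseDAG(
            disease="a",
            nodes=frozenset({"a", "b", "c", "r"}),
            edges=frozenset({("a", "b"), ("a", "c"), ("b", "r"), ("c", "r")}),
        )
        p = semantic_profile(dag, half_delta)
        assert p.contributions["r"] == pytest.approx(0.25)
        assert p.dv == pytest.approx(2.25)

    def test_cycle_detected(self, half_delta):
        dag = DiseaseDAG(
            disease="a",
            nodes=frozenset({"a", "b", "c"}),
            edges=frozenset({("a", "b"), ("b", "c"), ("c", "b")}),
        )
        with pytest.raises(InvalidDAGError):
            semantic_profile(dag, half_delta)

    def test_self_similarity_is_one(self, chain_dag, half_delta):
        p = semantic_profile(chain_dag, half_delta)
        assert semantic_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_dags_zero(self, half_delta):
        pa = semantic_profile(
            DiseaseDAG("a", frozenset({"a"}), frozenset()), half_delta)
        pb = semantic_profile(
            DiseaseDAG("b", frozenset({"b"}), frozenset()), half_delta)
        assert semantic_similarity(pa, pb) == 0.0

    def test_sibling_hand_value(self, half_delta):
        # a and e are both children of b; b is a child of c
        pa = semantic_profile(
            DiseaseDAG("a", frozenset("abc"), frozenset({("a", "b"), ("b", "c")})),
            half_delta)
        pe = semantic_profile(
            DiseaseDAG("e", frozenset("ebc"), frozenset({("e", "b"), ("b", "c")})),
            half_delta)
        assert semantic_similarity(pa, pe) == pytest.approx(1.5 / 3.5)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dag = random_dag(rng, int(rng.integers(2, 13)))
        delta = float(rng.uniform(0.2, 0.9))
        p = semantic_profile(dag, SemanticConfig(delta=delta))
        expected, dv = semantic_oracle(dag, delta)
        assert p.contributions == pytest.approx(expected)
        assert p.dv == pytest.approx(dv)

    def test_similarity_increases_with_delta_on_chains(self):
        # deeper shared ancestry counts more as delta grows
        a = DiseaseDAG("a", frozenset("abc"), frozenset({("a", "b"), ("b", "c")}))
        e = DiseaseDAG("e", frozenset("ebc"), frozenset({("e", "b"), ("b", "c")}))
        values = []
        for delta in (0.2, 0.5, 0.8):
            cfg = SemanticConfig(delta=delta)
            values.append(
                semantic_similarity(semantic_profile(a, cfg), semantic_profile(e, cfg))
            )
        assert values == sorted(values)

    def test_matrix_masks_diseases_without_dags(self, chain_dag, half_delta):
        DS = semantic_similarity_matrix({"a": chain_dag}, ("a", "z"), half_delta)
        assert DS.mask[0, 0] and not DS.mask[1, 1] and not DS.mask[0, 1]


def bma_bruteforce(d1, d2, sim):
    total = sum(max(sim[a][b] for b in d2) for a in d1)
    total += sum(max(sim[a][b] for a in d1) for b in d2)
    return total / (len(d1) + len(d2))


class TestFunctionalSimilarity:
    @staticmethod
    def _ds(names, values):
        return SimilarityMatrix.total(np.array(values, dtype=float), tuple(names),
                                      "semantic")

    def test_hand_values(self):
        DS = self._ds(["da", "db"], [[1.0, 0.4], [0.4, 1.0]])
        MF = functional_similarity(
            {"m1": {"da"}, "m2": {"db"}, "m3": {"da", "db"}}, DS)
        i, j, k = MF.pos("m1"), MF.pos("m2"), MF.pos("m3")
        assert MF.values[i, j] == pytest.approx(0.4)
        assert MF.values[k, j] == pytest.approx((0.4 + 1 + 1) / 3)
        assert MF.values[i, i] == 1.0

    def test_empty_disease_set_masked(self):
        DS = self._ds(["da"], [[1.0]])
        MF = functional_similarity({"m1": {"da"}, "m2": set()}, DS)
        j = MF.pos("m2")
        assert not MF.mask[j].any()  # including its own diagonal

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_max_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        diseases = [f"d{i}" for i in range(6)]
        raw = rng.random((6, 6))
        sym = np.clip((raw + raw.T) / 2, 0, 1)
        np.fill_diagonal(sym, 1.0)
        DS = self._ds(diseases, sym)
        sim = {a: {b: sym[i, j] for j, b in enumerate(diseases)}
               for i, a in enumerate(diseases)}
        sets = {
            f"m{k}": set(rng.choice(diseases,
                                    size=int(rng.integers(1, 4)), replace=False))
            for k in range(5)
        }
        MF = functional_similarity(sets, DS)
        for a in sets:
            for b in sets:
                expected = 1.0 if a == b else bma_bruteforce(sets[a], sets[b], sim)
                assert MF.values[MF.pos(a), MF.pos(b)] == pytest.approx(expected)
                assert 0.0 <= MF.values[MF.pos(a), MF.pos(b)] <= 1.0
        assert np.allclose(MF.values, MF.values.T)


class TestLoadFunctionalSimilarity:
    def test_full_coverage(self, tmp_path):
        f = tmp_path / "mf.tsv"
        f.write_text("\tm1\tm2\nm1\t1.0\t0.3\nm2\t0.3\t1.0\n")
        MF = load_functional_similarity(f, ("m1", "m2"))
        assert MF.mask.all()
        assert MF.values[0, 1] == pytest.approx(0.3)

    def test_partial_coverage_masks_missing(self, tmp_path):
        f = tmp_path / "mf.tsv"
        f.write_text("\tm1\nm1\t1.0\n")
        MF = load_functional_similarity(f, ("m1", "m2"))
        assert MF.mask[0, 0] and not MF.mask[1, 1] and not MF.mask[0, 1]

    def test_asymmetric_rejected(self, tmp_path):
        f = tmp_path / "mf.tsv"
        f.write_text("\tm1\tm2\nm1\t1.0\t0.3\nm2\t0.7\t1.0\n")
        with pytest.raises(DataValidationError):
            load_functional_similarity(f, ("m1", "m2"))
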