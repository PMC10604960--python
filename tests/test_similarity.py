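import numpy as np
import pytest

from mdalink.similarity import (
    AssociationMatrix,
    DegenerateBandwidthError,
    DiseaseDAG,
    DomainError,
    IdentifierError,
    SimilarityMatrix,
    StructureError,
    aggregate_similarity,
    build_hetero_adjacency,
    build_similarity_adjacency,
    disease_semantic_similarity,
    functional_similarity_matrix,
    gip_bandwidth,
    gip_similarity,
    mirna_functional_similarity,
    semantic_profile,
    semantic_similarity_matrix,
)

from conftest import oracle_semantic_contributions, random_dag


class TestSemanticProfile:
    def test_chain(self, chain_dag):
        prof = semantic_profile(chain_dag, "A")
        assert prof.contributions == {"A": 1.0, "P": 0.5, "R": 0.25}
        assert prof.semantic_value == pytest.approx(1.75)

    def test_isolated_root(self):
        dag = DiseaseDAG(terms=["X"], parent_edges=set())
        prof = semantic_profile(dag, "X")
        assert prof.contributions == {"X": 1.0}
        assert prof.semantic_value == 1.0

    def test_diamond(self, diamond_dag):
        prof = semantic_profile(diamond_dag, "A")
        assert prof.contributions["R"] == pytest.approx(0.25)
        assert prof.semantic_value == pytest.approx(2.25)

    def test_root_contribution_always_one(self, sibling_dag):
        for term in sibling_dag.terms:
            assert semantic_profile(sibling_dag, term).contributions[term] == 1.0

    def test_unknown_root(self, chain_dag):
        with pytest.raises(IdentifierError):
            semantic_profile(chain_dag, "nope")

    def test_covers_exactly_ancestors(self, sibling_dag):
        prof = semantic_profile(sibling_dag, "B")
        assert set(prof.contributions) == {"B", "P", "R"}

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            dag = random_dag(rng, int(rng.integers(1, 13)))
            root = dag.terms[int(rng.integers(len(dag.terms)))]
            prof = semantic_profile(dag, root)
            oracle = oracle_semantic_contributions(dag, root)
            assert prof.contributions.keys() == oracle.keys()
            for t, v in oracle.items():
                assert prof.contributions[t] == pytest.approx(v, abs=1e-12)

    def test_semantic_value_at_least_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(1, 10)))
            for t in dag.terms:
                assert semantic_profile(dag, t).semantic_value >= 1.0


class TestDiseaseDAG:
    def test_cycle_rejected(self):
        with pytest.raises(StructureError):
            DiseaseDAG(terms=["a", "b"], parent_edges={("a", "b"), ("b", "a")})

    def test_unregistered_endpoint_rejected(self):
        with pytest.raises(StructureError):
            DiseaseDAG(terms=["a"], parent_edges={("a", "zzz")})

    @pytest.mark.parametrize("decay", [0.0, -0.1, 1.5])
    def test_bad_decay(self, decay):
        with pytest.raises(ValueError):
            DiseaseDAG(terms=["a"], parent_edges=set(), decay=decay)


class TestDiseaseSemanticSimilarity:
    def test_self_similarity_is_one(self, sibling_dag):
        for t in sibling_dag.terms:
            assert disease_semantic_similarity(sibling_dag, t, t) == pytest.approx(1.0)

    def test_siblings_worked_example(self, sibling_dag):
        # shared {P, R}: (0.5+0.5+0.25+0.25) / (1.75+1.75) = 3/7
        val = disease_semantic_similarity(sibling_dag, "A", "B")
        assert val == pytest.approx(3 / 7, abs=1e-9)

    def test_disjoint_components_zero(self):
        dag = DiseaseDAG(terms=["a", "b", "x", "y"], parent_edges={("a", "b"), ("x", "y")})
        assert disease_semantic_similarity(dag, "a", "x") == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(2, 12)))
            t1, t2 = rng.choice(len(dag.terms), size=2, replace=False)
            a, b = dag.terms[int(t1)], dag.terms[int(t2)]
            v1 = disease_semantic_similarity(dag, a, b)
            v2 = disease_semantic_similarity(dag, b, a)
            assert v1 == pytest.approx(v2, abs=1e-9)
            assert 0.0 <= v1 <= 1.0

    def test_matrix_matches_pairwise(self, sibling_dag):
        mat = semantic_similarity_matrix(sibling_dag)
        for i, a in enumerate(mat.ids):
            for j, b in enumerate(mat.ids):
                assert mat.values[i, j] == pytest.approx(
                    disease_semantic_similarity(sibling_dag, a, b), abs=1e-12
                )


class TestMirnaFunctionalSimilarity:
    @pytest.fixture
    def dss(self, sibling_dag):
        return semantic_similarity_matrix(sibling_dag, ["A", "B"])

    def test_self_similarity(self, dss):
        assoc = AssociationMatrix(["m1", "m2"], ["A", "B"], np.array([[1, 0], [0, 1]]))
        assert mirna_functional_similarity(dss, assoc, "m1", "m1") == pytest.approx(1.0)

    def test_single_disease_each(self, dss):
        assoc = AssociationMatrix(["m1", "m2"], ["A", "B"], np.array([[1, 0], [0, 1]]))
        val = mirna_functional_similarity(dss, assoc, "m1", "m2")
        assert val == pytest.approx(3 / 7, abs=1e-9)

    def test_one_vs_two_diseases(self, dss):
        # D(m1)={A}, D(m2)={A,B}: (1 + (1 + 3/7)) / 3 = 17/21
        assoc = AssociationMatrix(["m1", "m2"], ["A", "B"], np.array([[1, 0], [1, 1]]))
        val = mirna_functional_similarity(dss, assoc, "m1", "m2")
        assert val == pytest.approx(17 / 21, abs=1e-9)

    def test_isolated_mirna_raises(self, dss):
        assoc = AssociationMatrix(["m1", "m2"], ["A", "B"], np.array([[1, 0], [0, 0]]))
        with pytest.raises(DomainError):
            mirna_functional_similarity(dss, assoc, "m1", "m2")

    def test_matrix_agrees_and_isolated_rows_zero(self, dss):
        assoc = AssociationMatrix(
            ["m1", "m2", "m3"], ["A", "B"], np.array([[1, 0], [1, 1], [0, 0]])
        )
        mat = functional_similarity_matrix(dss, assoc)
        assert mat.kind == "MFS"
        assert mat.values[0, 1] == pytest.approx(17 / 21, abs=1e-9)
        assert (mat.values[2] == 0).all()


class TestGIP:
    def test_bandwidth_two_unit_profiles(self):
        assert gip_bandwidth([(1, 0), (0, 1)]) == pytest.approx(1.0)

    def test_bandwidth_single_profile(self):
        assert gip_bandwidth([(1, 1, 1, 1)]) == pytest.approx(0.25)

    def test_bandwidth_all_zero(self):
        with pytest.raises(DegenerateBandwidthError):
            gip_bandwidth([(0, 0)])

    def test_two_disease_worked_example(self):
        # IP(d1)=(1,0), IP(d2)=(0,1): theta=1, similarity exp(-2)
        assoc = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [0, 1]]))
        sim = gip_similarity(assoc, "disease")
        assert sim.kind == "DGS"
        assert sim.values[0, 1] == pytest.approx(np.exp(-2), abs=1e-9)

    def test_identical_profiles_similarity_one(self):
        assoc = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.array([[1, 0], [1, 0]]))
        sim = gip_similarity(assoc, "mirna")
        assert sim.values[0, 1] == pytest.approx(1.0)

    def test_symmetry_and_unit_diagonal(self, toy_assoc):
        for axis, kind in [("disease", "DGS"), ("mirna", "MGS")]:
            sim = gip_similarity(toy_assoc, axis)
            assert sim.kind == kind
            np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-9)
            np.testing.assert_allclose(np.diag(sim.values), 1.0)
            assert sim.values.min() >= 0 and sim.values.max() <= 1

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        entries = (rng.random((6, 5)) < 0.4).astype(int)
        entries[entries.sum(1) == 0, 0] = 1
        mirnas = [f"m{i}" for i in range(6)]
        assoc = AssociationMatrix(mirnas, [f"d{j}" for j in range(5)], entries)
        sim = gip_similarity(assoc, "mirna").values
        perm = rng.permutation(6)
        assoc_p = AssociationMatrix(
            [mirnas[i] for i in perm], [f"d{j}" for j in range(5)], entries[perm]
        )
        sim_p = gip_similarity(assoc_p, "mirna").values
        np.testing.assert_allclose(sim_p, sim[np.ix_(perm, perm)], atol=1e-12)


class TestAggregation:
    def _sims(self, primary_vals, fallback_vals):
        ids = ["x", "y"]
        p = SimilarityMatrix(ids, np.array(primary_vals, dtype=float), "MFS")
        f = SimilarityMatrix(ids, np.array(fallback_vals, dtype=float), "MGS")
        return p, f

    def test_primary_wins_when_nonzero(self):
        p, f = self._sims([[1, 0.6], [0.6, 1]], [[1, 0.2], [0.2, 1]])
        assert aggregate_similarity(p, f).values[0, 1] == 0.6

    def test_fallback_fills_zero(self):
        p, f = self._sims([[1, 0.0], [0.0, 1]], [[1, 0.3], [0.3, 1]])
        out = aggregate_similarity(p, f)
        assert out.kind == "MF"
        assert out.values[0, 1] == 0.3

    def test_all_zero_primary_equals_fallback(self):
        ids = ["x", "y"]
        p = SimilarityMatrix(ids, np.zeros((2, 2)), "MFS")
        f = SimilarityMatrix(ids, np.array([[1, 0.3], [0.3, 1]]), "MGS")
        np.testing.assert_array_equal(aggregate_similarity(p, f).values, f.values)

    def test_registry_mismatch(self):
        p = SimilarityMatrix(["x", "y"], np.eye(2), "MFS")
        f = SimilarityMatrix(["x", "z"], np.eye(2), "MGS")
        with pytest.raises(ValueError):
            aggregate_similarity(p, f)

    def test_never_loses_information(self):
        rng = np.random.default_rng(5)
        vals = rng.random((4, 4))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        mask = rng.random((4, 4)) < 0.5
        mask &= mask.T
        np.fill_diagonal(mask, False)
        primary_vals = np.where(mask, 0.0, vals)
        ids = list("abcd")
        p = SimilarityMatrix(ids, primary_vals, "MFS")
        f = SimilarityMatrix(ids, vals, "MGS")
        out = aggregate_similarity(p, f).values
        zero_out = out == 0
        assert (zero_out <= ((p.values == 0) & (f.values == 0))).all()


class TestAdjacencies:
    def test_threshold_zero_marks_nonzero(self):
        vals = np.array([[1, 0.4, 0], [0.4, 1, 0], [0, 0, 1.0]])
        sim = SimilarityMatrix(["a", "b", "c"], vals, "MFS")
        adj = build_similarity_adjacency(sim, 0.0)
        assert adj[0, 1] == 1 and adj[0, 2] == 0
        assert (adj == adj.T).all()

    def test_higher_threshold_prunes(self):
        vals = np.array([[1, 0.4], [0.4, 1.0]])
        sim = SimilarityMatrix(["a", "b"], vals, "MFS")
        assert build_similarity_adjacency(sim, 0.5).sum() == 0

    def test_identity_similarity_gives_empty_adjacency(self):
        sim = SimilarityMatrix(["a", "b"], np.eye(2), "MFS")
        assert build_similarity_adjacency(sim, 0.0).sum() == 0

    def test_bad_threshold(self):
        sim = SimilarityMatrix(["a"], np.eye(1), "MFS")
        with pytest.raises(ValueError):
            build_similarity_adjacency(sim, 1.0)

    def test_hetero_block_structure(self):
        assoc = AssociationMatrix(["m1", "m2"], ["d1", "d2"], np.eye(2, dtype=int))
        g = build_hetero_adjacency(assoc)
        assert g.shape == (4, 4)
        assert g.sum() == 4
        assert (g[:2, :2] == 0).all() and (g[2:, 2:] == 0).all()
        np.testing.assert_array_equal(g[:2, 2:], np.eye(2))

    def test_hetero_empty(self):
        assoc = AssociationMatrix(["m1"], ["d1"], np.zeros((1, 1), dtype=int))
        assert build_hetero_adjacency(assoc).sum() == 0

    def test_hetero_edge_count_doubles(self, toy_assoc):
        g = build_hetero_adjacency(toy_assoc)
        assert g.sum() == 2 * toy_assoc.n_associations
        assert (g == g.T).all()


class TestAssociationMatrix:
    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            AssociationMatrix(["m"], ["d"], np.array([[2]]))

    def test_rejects_duplicates(self):
        with pytest.raises(ValueError):
            AssociationMatrix(["m", "m"], ["d1", "d2"], np.zeros((2, 2), dtype=int))

    def test_without_pairs(self, toy_assoc):
        reduced = toy_assoc.without_pairs([("m1", "A")])
        assert reduced.entries[0, 0] == 0
        assert reduced.n_associations == toy_assoc.n_associations - 1
        assert reduced.provenance == "training-fold"
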