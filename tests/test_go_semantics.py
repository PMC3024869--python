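"""Ontology propagation, information content, Resnik/Lin similarity."""

import itertools
import math

import numpy as np
import pytest

from divergon.go_semantics import (
    AnnotationSet,
    GoDag,
    OntologyError,
    SemanticSimilarity,
    funcsim_by_coexpression_threshold,
    gene_pair_similarity,
    information_content,
    lin_similarity,
    minimum_subsumer,
    propagate_annotations,
    random_funcsim_control,
    representative_similarity,
)
from divergon.synthetic import SimulationConfig, simulate_ontology, simulate_genome

from _oracles import brute_force_ancestors, brute_force_min_subsumer


@pytest.fixture
def toy_dag():
    """root -> {parent, t3}; parent -> {t1, t2}; one BP subsystem."""
    parents = {
        "root": frozenset(),
        "parent": frozenset({"root"}),
        "t1": frozenset({"parent"}),
        "t2": frozenset({"parent"}),
        "t3": frozenset({"root"}),
    }
    subsystem = dict.fromkeys(parents, "BP")
    return GoDag(parents=parents, subsystem=subsystem)


@pytest.fixture
def toy_annotations():
    """8 genes: t1 and t2 cover 2 genes each, the t3 branch the other 4."""
    return AnnotationSet(
        by_subsystem={
            "BP": {
                "g1": frozenset({"t1"}),
                "g2": frozenset({"t1"}),
                "g3": frozenset({"t2"}),
                "g4": frozenset({"t2"}),
                "g5": frozenset({"t3"}),
                "g6": frozenset({"t3"}),
                "g7": frozenset({"t3"}),
                "g8": frozenset({"t3"}),
            }
        }
    )


def _random_dag(seed, depth=4, branching=3):
    cfg = SimulationConfig(seed=seed, dag_depth=depth, branching=branching,
                           n_h2h_pairs=10, n_chromosomes=1,
                           genes_per_chromosome=40)
    genes, truth, _, _ = simulate_genome(cfg)
    dag, annotations = simulate_ontology(cfg, truth, genes)
    return dag, annotations


class TestDagStructure:
    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            GoDag(
                parents={"a": frozenset({"b"}), "b": frozenset({"a"})},
                subsystem={"a": "BP", "b": "BP"},
            )

    def test_unknown_parent_rejected(self):
        with pytest.raises(OntologyError, match="unknown parent"):
            GoDag(parents={"a": frozenset({"zz"})}, subsystem={"a": "BP"})

    def test_obo_roundtrip(self, tmp_path):
        from divergon.synthetic import _write_obo

        dag, _ = _random_dag(3)
        path = tmp_path / "toy.obo"
        _write_obo(dag, str(path))
        loaded = GoDag.from_obo(str(path))
        assert loaded.parents == dag.parents
        assert loaded.subsystem == dag.subsystem

    def test_ancestors_match_brute_force(self):
        dag, _ = _random_dag(4)
        for term in dag.terms:
            assert dag.ancestors(term) == brute_force_ancestors(dag.parents, term)


class TestPropagation:
    def test_closure_adds_all_ancestors(self, toy_dag):
        raw = AnnotationSet(by_subsystem={"BP": {"g": frozenset({"t1"})}})
        closed = propagate_annotations(toy_dag, raw)
        assert closed.terms_of("g", "BP") == {"t1", "parent", "root"}

    def test_idempotence(self, toy_dag, toy_annotations):
        once = propagate_annotations(toy_dag, toy_annotations)
        twice = propagate_annotations(toy_dag, once)
        assert once.by_subsystem == twice.by_subsystem

    def test_unknown_terms_listed(self, toy_dag):
        raw = AnnotationSet(by_subsystem={"BP": {"g": frozenset({"bogus"})}})
        with pytest.raises(OntologyError, match="bogus"):
            propagate_annotations(toy_dag, raw)

    def test_closure_matches_brute_force_on_random_dag(self):
        dag, annotations = _random_dag(5)
        closed = propagate_annotations(dag, annotations)
        for ss, genes in annotations.by_subsystem.items():
            for g, ts in genes.items():
                expected = set(ts)
                for t in ts:
                    expected |= brute_force_ancestors(dag.parents, t)
                assert closed.terms_of(g, ss) == expected


class TestInformationContent:
    def test_root_ic_zero_and_halving_gives_ln2(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, propagate_annotations(toy_dag, toy_annotations))
        assert ic.ic["root"] == 0.0 and ic.p["root"] == 1.0
        # parent covers g1..g4 = 4 of 8 genes
        assert ic.ic["parent"] == pytest.approx(math.log(2))
        assert ic.ic["t1"] == pytest.approx(math.log(4))

    def test_monotone_along_edges(self):
        dag, annotations = _random_dag(6)
        ic = information_content(dag, propagate_annotations(dag, annotations))
        for child, parents in dag.parents.items():
            if child not in ic:
                continue
            for p in parents:
                assert ic.ic[child] >= ic.ic[p] - 1e-12


class TestMinimumSubsumerAndLin:
    def test_identity_and_sibling_cases(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, propagate_annotations(toy_dag, toy_annotations))
        term, val = minimum_subsumer(toy_dag, ic, "t1", "t1")
        assert term == "t1" and val == pytest.approx(ic.ic["t1"])
        term, val = minimum_subsumer(toy_dag, ic, "t1", "t2")
        assert term == "parent" and val == pytest.approx(math.log(2))
        # only the root subsumes the two branches
        term, val = minimum_subsumer(toy_dag, ic, "t1", "t3")
        assert term == "root" and val == 0.0

    def test_lin_values(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, propagate_annotations(toy_dag, toy_annotations))
        assert lin_similarity(ic, "t1", "t1", ic.ic["t1"]) == pytest.approx(1.0)
        assert lin_similarity(ic, "t1", "t3", 0.0) == 0.0
        assert lin_similarity(ic, "root", "root", 0.0) == 0.0  # 0/0 guarded
        # IC(t1)=IC(t2)=ln4, IC_ms=ln2 -> 2 ln2 / (2 ln4) = 0.5
        assert lin_similarity(ic, "t1", "t2", math.log(2)) == pytest.approx(0.5)

    def test_resnik_bounded_by_min_ic_and_matches_brute_force(self):
        dag, annotations = _random_dag(7)
        ic = information_content(dag, propagate_annotations(dag, annotations))
        terms = sorted(t for t in dag.terms if t in ic)
        by_ss = {}
        for t in terms:
            by_ss.setdefault(dag.subsystem[t], []).append(t)
        for ss, ss_terms in by_ss.items():
            for t1, t2 in itertools.combinations(ss_terms[:25], 2):
                term, val = minimum_subsumer(dag, ic, t1, t2)
                bf_term, bf_val = brute_force_min_subsumer(dag.parents, ic.ic, t1, t2)
                assert (term, val) == (bf_term, pytest.approx(bf_val))
                assert val <= min(ic.ic[t1], ic.ic[t2]) + 1e-12

    def test_cross_subsystem_rejected(self):
        dag, annotations = _random_dag(8)
        ic = information_content(dag, propagate_annotations(dag, annotations))
        bp = next(t for t in dag.terms if dag.subsystem[t] == "BP")
        mf = next(t for t in dag.terms if dag.subsystem[t] == "MF")
        with pytest.raises(OntologyError):
            minimum_subsumer(dag, ic, bp, mf)


class TestGenePairSimilarity:
    def test_shared_informative_term_gives_one(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, propagate_annotations(toy_dag, toy_annotations))
        sim = gene_pair_similarity(toy_dag, ic, toy_annotations, "g1", "g2", "BP")
        assert sim == pytest.approx(1.0)

    def test_unannotated_gene_is_undefined(self, toy_dag, toy_annotations):
        ic = information_content(toy_dag, propagate_annotations(toy_dag, toy_annotations))
        assert gene_pair_similarity(toy_dag, ic, toy_annotations, "g1", "nope", "BP") is None

    def test_max_combine_matches_term_by_term_oracle(self):
        dag, annotations = _random_dag(9)
        ic = information_content(dag, propagate_annotations(dag, annotations))
        engine = SemanticSimilarity(dag, ic, annotations, combine="max")
        ss = "BP"
        genes = sorted(annotations.by_subsystem[ss])[:6]
        for g1, g2 in itertools.combinations(genes, 2):
            got = engine.gene_pair(g1, g2, ss)
            ts1 = [t for t in annotations.terms_of(g1, ss) if t in ic]
            ts2 = [t for t in annotations.terms_of(g2, ss) if t in ic]
            expected = max(
                lin_similarity(
                    ic, a, b, brute_force_min_subsumer(dag.parents, ic.ic, a, b)[1]
                )
                for a in ts1
                for b in ts2
            )
            assert got == pytest.approx(expected)

    def test_lin_symmetry_and_range(self):
        dag, annotations = _random_dag(10)
        ic = information_content(dag, propagate_annotations(dag, annotations))
        engine = SemanticSimilarity(dag, ic, annotations)
        terms = [t for t in sorted(dag.terms) if dag.subsystem[t] == "MF" and t in ic]
        for t1, t2 in itertools.combinations(terms[:12], 2):
            v = engine.term_sim(t1, t2)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(engine.term_sim(t2, t1))

    @pytest.mark.parametrize(
        "values, expected",
        [
            ({"BP": 0.3, "MF": 0.7, "CC": None}, 0.7),
            ({"BP": 0.4, "MF": 0.4, "CC": 0.4}, 0.4),
            ({"BP": None, "MF": None, "CC": 0.51}, 0.51),
            ({"BP": None, "MF": None, "CC": None}, None),
        ],
    )
    def test_representative_is_max_over_defined(self, values, expected):
        assert representative_similarity(values) == expected


class TestThresholdsAndControl:
    def test_threshold_table_no_filtering_and_empty_flag(self):
        pairs = [("a", "b"), ("c", "d")]
        funcsim = {("a", "b"): 0.4, ("c", "d"): 0.8}
        pcc = {("a", "b"): 0.1, ("c", "d"): 0.3}
        df = funcsim_by_coexpression_threshold(pairs, funcsim, pcc, [-1.0, 0.9])
        assert df.loc[0, "mean_similarity"] == pytest.approx(0.6)
        assert bool(df.loc[1, "empty"]) is True

    def test_planted_similarity_pcc_relation_is_monotone(self):
        rng = np.random.default_rng(2)
        pairs = [(f"a{i}", f"b{i}") for i in range(400)]
        pcc = {p: rng.uniform(-1, 1) for p in pairs}
        funcsim = {
            p: float(np.clip(0.2 + 0.5 * pcc[p] + rng.normal(0, 0.05), 0, 1))
            for p in pairs
        }
        df = funcsim_by_coexpression_threshold(pairs, funcsim, pcc, [-1.0, 0.0, 0.5])
        means = df["mean_similarity"].tolist()
        assert means[0] < means[1] < means[2]

    def test_random_control_is_seeded_and_sized(self):
        dag, annotations = _random_dag(11)
        ic = information_content(dag, propagate_annotations(dag, annotations))
        engine = SemanticSimilarity(dag, ic, annotations)
        a = random_funcsim_control(engine, n_pairs=20, n_iter=100, seed=5)
        b = random_funcsim_control(engine, n_pairs=20, n_iter=100, seed=5)
        assert len(a) == 100
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))
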