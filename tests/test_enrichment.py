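"""Ontology closure, Fisher's exact test, enrichment, and term selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from acetylatlas.config import PipelineConfig
from acetylatlas.enrichment import (
    CycleError,
    EnrichmentMatrix,
    OntologyDAG,
    ancestor_closure,
    fisher_exact_2x2,
    prune_overlapping_terms,
    prune_parent_child,
    rank_unique_terms,
    select_variable_terms,
    tissue_enrichment,
)
from acetylatlas.quantify import DetectionPattern


def reachable(parents: dict[str, set[str]], start: str) -> set[str]:
    """Brute-force upward reachability oracle."""
    seen, frontier = set(), {start}
    while frontier:
        nxt = set()
        for t in frontier:
            for p in parents.get(t, ()):  # child -> parent
                if p not in seen:
                    seen.add(p)
                    nxt.add(p)
        frontier = nxt
    return seen


class TestAncestorClosure:
    def test_chain(self):
        dag = OntologyDAG({"c": {"b"}, "b": {"a"}})
        closed = ancestor_closure(dag, {"prot": {"c"}})
        assert closed["prot"] == {"c", "b", "a"}

    def test_root_only(self):
        dag = OntologyDAG({"b": {"a"}})
        closed = ancestor_closure(dag, {"prot": {"a"}})
        assert closed["prot"] == {"a"}

    def test_diamond_matches_reachability_oracle(self):
        parents = {"d": {"b", "c"}, "b": {"a"}, "c": {"a"}}
        dag = OntologyDAG(parents)
        closed = ancestor_closure(dag, {"prot": {"d"}})
        assert closed["prot"] == {"d"} | reachable(parents, "d")
        assert closed["prot"] == {"d", "b", "c", "a"}

    def test_idempotent(self):
        parents = {"d": {"b", "c"}, "b": {"a"}, "c": {"a"}, "e": {"d"}}
        dag = OntologyDAG(parents)
        once = ancestor_closure(dag, {"p": {"e", "c"}})
        twice = ancestor_closure(dag, once)
        assert once == twice

    def test_cycle_detected(self):
        dag = OntologyDAG({"a": {"b"}, "b": {"a"}})
        with pytest.raises(CycleError):
            ancestor_closure(dag, {"p": {"a"}})


def enumeration_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: sum hypergeometric point probabilities over all
    fixed-margin tables at least as extreme (one-sided, greater)."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    denom = math.comb(n, col1)
    total = 0
    for x in range(a, hi + 1):
        total += math.comb(row1, x) * math.comb(n - row1, col1 - x)
    return total / denom if denom else 1.0


class TestFisherExact:
    def test_worked_examples(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(0.5)
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 6)

    def test_degenerate_tables(self):
        assert fisher_exact_2x2([[0, 0], [3, 5]]) == 1.0
        assert fisher_exact_2x2([[2, 3], [0, 0]]) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_matches_enumeration_small_n(self):
        """Exhaustive check against the fixed-margin enumeration oracle
        for every table with N <= 20 (the full N <= 30 sweep runs in the
        acceptance suite)."""
        for n in range(21):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                expected = enumeration_pvalue(a, b, c, d)
                assert fisher_exact_2x2([[a, b], [c, d]]) == pytest.approx(
                    expected, rel=1e-9
                ), (a, b, c, d)


def make_detection(data: dict[str, dict[str, bool]]) -> DetectionPattern:
    df = pd.DataFrame(data).T.astype("boolean").fillna(False).astype(bool)
    return DetectionPattern(df, df.sum(axis=1))


class TestTissueEnrichment:
    def test_zero_acetyl_tissue_gives_p_one(self):
        det = make_detection({"s1": {"liver": True, "heart": False}})
        em = tissue_enrichment(
            det, {"s1": "P1"}, {"P1": {"T1"}, "P2": {"T1"}},
            universe={"P1", "P2", "P3", "P4"},
        )
        assert (em.pvalues["heart"] == 1.0).all()
        assert (em.pvalues["liver"] <= 1.0).all()

    def test_universal_term_never_enriched(self):
        det = make_detection({"s1": {"liver": True}})
        annotations = {p: {"T1"} for p in "ABCD"}
        em = tissue_enrichment(det, {"s1": "A"}, annotations, set("ABCD"))
        assert (em.pvalues.loc["T1"] == 1.0).all()

    def test_planted_single_tissue_term(self):
        """A term annotating exactly one tissue's acetyl proteins is strongly
        enriched there and nowhere else."""
        sites = {f"s{i}": {"liver": True} for i in range(6)}
        sites.update({f"t{i}": {"liver": True, "heart": True} for i in range(4)})
        det = make_detection(sites)
        site_proteins = {k: k.upper() for k in sites}
        universe = {k.upper() for k in sites} | {f"U{i}" for i in range(90)}
        annotations = {f"S{i}": {"TERM"} for i in range(6)}
        em = tissue_enrichment(det, site_proteins, annotations, universe)
        assert em.pvalues.loc["TERM", "liver"] < 1e-3
        assert em.pvalues.loc["TERM", "heart"] >= 0.05

    def test_empty_universe_rejected(self):
        det = make_detection({"s1": {"liver": True}})
        with pytest.raises(ValueError):
            tissue_enrichment(det, {"s1": "P1"}, {}, set())


class TestSelectVariableTerms:
    def make_em(self, vectors: dict[str, list[float]], sd_ddof=1):
        nl = pd.DataFrame(
            vectors, index=[f"tis{i}" for i in range(15)]
        ).T
        return EnrichmentMatrix(10.0 ** (-nl), sd_ddof=sd_ddof)

    @pytest.mark.parametrize("sd_ddof", [0, 1])
    def test_fourteen_zeros_one_four_retained(self, sd_ddof):
        """Vector of 14 zeros and one 4: sample sd 1.033, population sd
        0.998 — retained under both conventions."""
        em = self.make_em({"T": [0.0] * 14 + [4.0]}, sd_ddof=sd_ddof)
        cfg = PipelineConfig(sd_ddof=sd_ddof)
        sd = np.std([0.0] * 14 + [4.0], ddof=sd_ddof)
        assert sd > 0.6
        assert select_variable_terms(em, cfg) == ["T"]

    def test_constant_vectors_rejected(self):
        em = self.make_em({"flat5": [5.0] * 15, "flat0": [0.0] * 15})
        assert select_variable_terms(em) == []


class TestPruning:
    def test_identical_sets_keep_one(self):
        sets = {"A": {"p1", "p2"}, "B": {"p1", "p2"}}
        assert prune_overlapping_terms(["A", "B"], sets) == ["A"]

    def test_disjoint_sets_keep_both(self):
        sets = {"A": {"p1"}, "B": {"p2"}}
        assert prune_overlapping_terms(["A", "B"], sets) == ["A", "B"]

    def test_overlap_exactly_ninety_percent_keeps_both(self):
        small = {f"p{i}" for i in range(10)}          # |A|=10
        big = set(small) - {"p0"} | {f"q{i}" for i in range(11)}  # inter=9
        sets = {"A": small, "B": big}
        assert len(small & big) / min(len(small), len(big)) == 0.9
        assert prune_overlapping_terms(["A", "B"], sets) == ["A", "B"]

    def test_keeps_strongest_of_pair(self):
        sets = {"A": {"p1", "p2"}, "B": {"p1", "p2"}}
        nl = pd.DataFrame({"t1": [1.0, 5.0]}, index=["A", "B"])
        em = EnrichmentMatrix(10.0 ** (-nl))
        assert prune_overlapping_terms(["A", "B"], sets, em) == ["B"]

    def test_parent_child_keeps_descendant(self):
        dag = OntologyDAG({"child": {"parent"}, "parent": {"root"}})
        assert prune_parent_child(["parent", "child"], dag) == ["child"]
        assert prune_parent_child(["child", "other"], dag) == ["child", "other"]
        # 3-term chain: only the deepest survives
        assert prune_parent_child(["root", "parent", "child"], dag) == ["child"]


class TestRankUniqueTerms:
    def make_em(self, vectors):
        nl = pd.DataFrame(vectors).T
        return EnrichmentMatrix(10.0 ** (-nl))

    def test_tissue_specific_term_ranks_first(self):
        em = self.make_em({
            "brainy": {"brain": 5.0, "liver": 0.0, "heart": 0.0},
            "shared": {"brain": 3.0, "liver": 3.0, "heart": 2.9},
        })
        ranked = rank_unique_terms(em, "brain")
        assert ranked.index[0] == "brainy"

    def test_constant_term_scores_zero(self):
        em = self.make_em({"flat": {"brain": 2.0, "liver": 2.0, "heart": 2.0}})
        assert rank_unique_terms(em, "brain")["flat"] == 0.0

    def test_affine_invariance(self):
        base = {"brain": 4.0, "liver": 1.0, "heart": 0.5}
        em1 = self.make_em({"T": base})
        em2 = self.make_em({"T": {k: 3.0 * v + 2.0 for k, v in base.items()}})
        s1 = rank_unique_terms(em1, "brain")["T"]
        s2 = rank_unique_terms(em2, "brain")["T"]
        assert s1 == pytest.approx(s2)


def test_select_prune_pipeline_subset_and_stable():
    """The select -> prune chain returns a subset of its input and is
    invariant to input order."""
    rng = np.random.default_rng(4)
    terms = [f"T{i}" for i in range(12)]
    nl = pd.DataFrame(
        rng.exponential(1.0, size=(12, 15)), index=terms,
        columns=[f"tis{j}" for j in range(15)],
    )
    nl.iloc[::3, 0] = 4.0                      # give some terms a spike
    em = EnrichmentMatrix(10.0 ** (-nl))
    sets = {
        t: {f"p{j}" for j in rng.choice(50, size=10, replace=False)}
        for t in terms
    }
    selected = select_variable_terms(em)
    assert set(selected) <= set(terms)
    kept = prune_overlapping_terms(selected, sets, em)
    assert set(kept) <= set(selected)
    kept_rev = prune_overlapping_terms(selected[::-1], sets, em)
    assert kept == kept_rev


def test_read_obo_is_a_edges(tmp_path):
    from acetylatlas.enrichment import read_obo

    obo = """format-version: 1.2

[Term]
id: GO:0000001
name: root

[Term]
id: GO:0000002
name: middle
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: leaf
is_a: GO:0000002 ! middle
"""
    (tmp_path / "mini.obo").write_text(obo)
    dag = read_obo(tmp_path / "mini.obo")
    assert dag.ancestors("GO:0000003") == {"GO:0000002", "GO:0000001"}


def test_read_edge_list(tmp_path):
    from acetylatlas.enrichment import read_edge_list

    (tmp_path / "edges.tsv").write_text(
        "# child\tparent\nGO:b\tGO:a\nGO:c\tGO:b\n"
    )
    dag = read_edge_list(tmp_path / "edges.tsv")
    assert dag.ancestors("GO:c") == {"GO:b", "GO:a"}
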