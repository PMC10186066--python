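import numpy as np
import pytest

from ogxpand.go_enrichment import (
    OntologyGraph,
    Term,
    bh_adjust,
    elim_test,
    go_test,
    induced_subgraph,
    propagate,
    read_obo,
)


def graph_from_edges(edges, namespace="BP", extra_terms=()):
    """edges: (child, parent) is_a pairs."""
    children = {c for c, _ in edges}
    parents = {p for _, p in edges}
    terms = {}
    for t in sorted(children | parents | set(extra_terms)):
        ps = tuple(sorted(p for c, p in edges if c == t))
        terms[t] = Term(term_id=t, name=t, namespace=namespace, parents=ps)
    return OntologyGraph(terms=terms)


OBO_TEXT = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: middle
namespace: biological_process
is_a: GO:0000001 ! root
relationship: part_of GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: biological_process
is_a: GO:0000002 ! middle

[Term]
id: GO:0000009
name: gone
namespace: biological_process
is_obsolete: true
is_a: GO:0000001

[Typedef]
id: part_of
name: part of
"""


class TestReadObo:
    def test_parse(self, tmp_path):
        p = tmp_path / "toy.obo"
        p.write_text(OBO_TEXT)
        g = read_obo(p)
        assert set(g.terms) == {"GO:0000001", "GO:0000002", "GO:0000003", "GO:0000009"}
        assert g.terms["GO:0000002"].parents == ("GO:0000001",)
        assert g.terms["GO:0000002"].part_of == ("GO:0000001",)
        assert g.terms["GO:0000003"].namespace == "BP"
        assert g.terms["GO:0000009"].obsolete

    def test_cyclic_rejected(self):
        with pytest.raises(ValueError, match="cyclic"):
            graph_from_edges([("A", "B"), ("B", "A")])

    def test_depth_and_ancestors(self):
        g = graph_from_edges([("C", "B"), ("B", "A")])
        assert g.ancestors("C") == {"A", "B"}
        assert g.depth("C") == 2 and g.depth("A") == 0


def closure_oracle(term, parents_of):
    """Independent recursive-DFS closure."""
    out = set()

    def rec(t):
        for p in parents_of.get(t, ()):
            if p not in out:
                out.add(p)
                rec(p)

    rec(term)
    return out


class TestPropagate:
    def test_chain(self):
        g = graph_from_edges([("B", "A")])
        assert propagate({"g1": {"B"}}, g) == {"g1": frozenset({"A", "B"})}

    def test_diamond(self):
        g = graph_from_edges([("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")])
        assert propagate({"g1": {"D"}}, g)["g1"] == frozenset("ABCD")

    def test_root_only_unchanged(self):
        g = graph_from_edges([("B", "A")])
        assert propagate({"g1": {"A"}}, g)["g1"] == frozenset({"A"})

    def test_unknown_term_dropped_with_log(self, caplog):
        g = graph_from_edges([("B", "A")])
        with caplog.at_level("WARNING"):
            out = propagate({"g1": {"B", "GO:missing"}}, g)
        assert out["g1"] == frozenset({"A", "B"})
        assert "GO:missing" in caplog.text

    def test_obsolete_dropped(self):
        terms = {
            "A": Term("A", "A", "BP"),
            "OBS": Term("OBS", "OBS", "BP", parents=("A",), obsolete=True),
        }
        g = OntologyGraph(terms=terms)
        assert propagate({"g1": {"OBS"}}, g)["g1"] == frozenset()

    def test_part_of_optional(self):
        terms = {
            "A": Term("A", "A", "BP"),
            "B": Term("B", "B", "BP", part_of=("A",)),
        }
        g = OntologyGraph(terms=terms)
        assert propagate({"g1": {"B"}}, g)["g1"] == frozenset({"B"})
        assert propagate({"g1": {"B"}}, g, include_part_of=True)["g1"] == frozenset(
            {"A", "B"}
        )

    def test_random_dags_match_dfs_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(60):
            n = int(rng.integers(2, 60))
            names = [f"T{i}" for i in range(n)]
            edges = []
            for i in range(1, n):
                for p in rng.choice(i, size=min(i, int(rng.integers(1, 3))),
                                    replace=False):
                    edges.append((names[i], names[int(p)]))
            g = graph_from_edges(edges, extra_terms=names)
            parents_of = {t: g.terms[t].parents for t in g.terms}
            gene_terms = {
                "g": {names[int(i)] for i in rng.choice(n, size=3)}
            }
            closed = propagate(gene_terms, g)["g"]
            expected = set(gene_terms["g"])
            for t in gene_terms["g"]:
                expected |= closure_oracle(t, parents_of)
            assert closed == frozenset(expected)


class TestBH:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    @pytest.mark.parametrize(
        "pvals, expected",
        [
            ([0.005, 0.04, 0.05], [0.015, 0.05, 0.05]),
            ([0.5], [0.5]),
            ([0.9, 0.1], [0.9, 0.2]),
            ([0.01, 0.9, 0.9, 0.9], [0.04, 0.9, 0.9, 0.9]),
            ([], []),
        ],
    )
    def test_more_hand_lists(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        for _ in range(10):
            pvals = list(rng.random(int(rng.integers(1, 40))))
            _, expected, _, _ = multipletests(pvals, method="fdr_bh")
            assert bh_adjust(pvals) == pytest.approx(list(expected), rel=1e-12)

    def test_monotone_and_capped(self):
        rng = np.random.default_rng(5)
        pvals = list(rng.random(100))
        adj = bh_adjust(pvals)
        assert max(adj) <= 1.0
        order = np.argsort(pvals)
        ranked = [adj[i] for i in order]
        assert all(a <= b for a, b in zip(ranked, ranked[1:]))


def _toy_universe():
    """20 background OGs; term planted in 7 of them, 4 of the 6 study OGs."""
    g = graph_from_edges([("GO:T", "GO:ROOT"), ("GO:OTHER", "GO:ROOT")])
    og_terms = {}
    for i in range(20):
        terms = {"GO:ROOT"}
        if i < 4 or i in (10, 11, 12):  # 7 background OGs carry GO:T
            terms.add("GO:T")
        if i % 2 == 0:
            terms.add("GO:OTHER")
        og_terms[f"og{i}"] = frozenset(terms)
    study = [f"og{i}" for i in (0, 1, 2, 3, 5, 7)]  # k=4 for GO:T
    background = [f"og{i}" for i in range(20)]
    return g, og_terms, study, background


class TestGoTest:
    def test_planted_urn_matches_hand_enumeration(self):
        g, og_terms, study, background = _toy_universe()
        results = go_test(study, background, og_terms, g, namespace="BP")
        by_id = {r.term_id: r for r in results}
        r = by_id["GO:T"]
        assert (r.urn.N, r.urn.K, r.urn.n, r.urn.k) == (20, 7, 6, 4)
        assert r.p_raw == pytest.approx(3010 / 38760, rel=1e-12)
        assert r.member_ogs == ("og0", "og1", "og2", "og3")

    def test_term_in_every_background_og_has_p_one(self):
        g, og_terms, study, background = _toy_universe()
        results = go_test(study, background, og_terms, g)
        by_id = {r.term_id: r for r in results}
        assert by_id["GO:ROOT"].p_raw == 1.0

    def test_min_annotated_prunes(self):
        g, og_terms, study, background = _toy_universe()
        results = go_test(study, background, og_terms, g, min_annotated=8)
        assert "GO:T" not in {r.term_id for r in results}

    def test_namespace_filter(self):
        g, og_terms, study, background = _toy_universe()
        assert go_test(study, background, og_terms, g, namespace="MF") == []

    def test_empty_study_warns_and_returns_empty(self, caplog):
        g, og_terms, _, background = _toy_universe()
        with caplog.at_level("WARNING"):
            assert go_test([], background, og_terms, g) == []

    def test_study_outside_background_rejected(self):
        g, og_terms, _, background = _toy_universe()
        with pytest.raises(ValueError, match="subset"):
            go_test(["og999"], background, og_terms, g)

    def test_sorted_by_p_then_id(self):
        g, og_terms, study, background = _toy_universe()
        results = go_test(study, background, og_terms, g)
        keys = [(r.p_raw, r.term_id) for r in results]
        assert keys == sorted(keys)

    def test_adjusted_p_present(self):
        g, og_terms, study, background = _toy_universe()
        results = go_test(study, background, og_terms, g)
        raw = [r.p_raw for r in results]
        adj = {r.term_id: r.p_adjusted for r in results}
        expected = bh_adjust(raw)
        for r, e in zip(results, expected):
            assert adj[r.term_id] == pytest.approx(e)

    def test_neg_log10(self):
        g, og_terms, study, background = _toy_universe()
        r = go_test(study, background, og_terms, g)[0]
        assert r.neg_log10_p == pytest.approx(-np.log10(r.p_raw))


class TestElim:
    def test_alpha_zero_reduces_to_classic(self):
        g, og_terms, study, background = _toy_universe()
        classic = go_test(study, background, og_terms, g)
        elim = elim_test(study, background, og_terms, g, elim_alpha=0.0)
        assert {(r.term_id, r.p_raw) for r in classic} == {
            (r.term_id, r.p_raw) for r in elim
        }

    def test_no_significant_child_identical(self):
        g, og_terms, study, background = _toy_universe()
        classic = go_test(study, background, og_terms, g)
        elim = elim_test(study, background, og_terms, g, elim_alpha=1e-12)
        assert {(r.term_id, r.p_raw) for r in classic} == {
            (r.term_id, r.p_raw) for r in elim
        }

    def test_significant_child_weakens_parent(self):
        # child fully explains the parent's signal
        g = graph_from_edges([("GO:CHILD", "GO:PARENT")])
        og_terms = {}
        for i in range(40):
            terms = set()
            if i < 10:
                terms = {"GO:CHILD", "GO:PARENT"}
            og_terms[f"og{i}"] = frozenset(terms)
        study = [f"og{i}" for i in range(8)]  # 8/8 carry the child term
        background = [f"og{i}" for i in range(40)]
        classic = {r.term_id: r.p_raw for r in go_test(study, background, og_terms, g)}
        elim = {
            r.term_id: r.p_raw
            for r in elim_test(study, background, og_terms, g, elim_alpha=0.05)
        }
        assert elim["GO:CHILD"] == classic["GO:CHILD"]
        assert elim["GO:PARENT"] >= classic["GO:PARENT"]
        assert elim["GO:PARENT"] == 1.0  # all annotated OGs removed

    def test_single_term_ontology(self):
        g = graph_from_edges([], extra_terms=["GO:ONLY"])
        og_terms = {f"og{i}": frozenset({"GO:ONLY"} if i < 5 else set())
                    for i in range(10)}
        study = ["og0", "og1"]
        classic = go_test(study, list(og_terms), og_terms, g)
        elim = elim_test(study, list(og_terms), og_terms, g, elim_alpha=0.05)
        assert [(r.term_id, r.p_raw) for r in classic] == [
            (r.term_id, r.p_raw) for r in elim
        ]


class TestInducedSubgraph:
    def test_chain(self):
        g = graph_from_edges([("D", "C"), ("C", "B"), ("B", "A")])
        edges = induced_subgraph(["D"], g)
        assert edges == [("B", "A", "is_a"), ("C", "B", "is_a"), ("D", "C", "is_a")]

    def test_siblings_share_ancestors_once(self):
        g = graph_from_edges([("B", "A"), ("C", "A")])
        edges = induced_subgraph(["B", "C"], g)
        assert edges == [("B", "A", "is_a"), ("C", "A", "is_a")]

    def test_empty_selection(self):
        g = graph_from_edges([("B", "A")])
        assert induced_subgraph([], g) == []

    def test_unknown_term(self):
        g = graph_from_edges([("B", "A")])
        with pytest.raises(KeyError):
            induced_subgraph(["Z"], g)


def test_planted_term_enriched_on_fixture(fixture_paths):
    import pandas as pd

    from ogxpand import formats_io

    table = formats_io.read_orthogroups(fixture_paths["orthogroups"])
    graph = read_obo(fixture_paths["obo"])
    raw = formats_io.read_go_map(fixture_paths["go_map"])
    closed = propagate(raw, graph)
    from ogxpand.go_enrichment import og_term_sets

    og_terms = og_term_sets({og: table.genes_of(og) for og in table.og_ids}, closed)
    study = list(pd.read_csv(fixture_paths["truth_go_study"], sep="\t")["og_id"])
    truth = pd.read_csv(fixture_paths["truth_terms"], sep="\t")
    planted = truth["term"][0]
    results = go_test(study, table.og_ids, og_terms, graph, min_annotated=1)
    by_id = {r.term_id: r for r in results}
    assert planted in by_id
    assert by_id[planted].urn.k == truth["n_study_annotated"][0]
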