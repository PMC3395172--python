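"""Token-graph conversion and the joint structural constraints."""

import random
from itertools import combinations

import pytest

from bioevents import synth
from bioevents.graph import (
    CANDIDATE_ANCHOR,
    OTHER,
    PROTEIN,
    GraphError,
    Token,
    TokenGraph,
    check_constraints,
    events_to_graph,
    graph_to_events,
    tokens_from_tsv,
    tokens_to_tsv,
)
from bioevents.standoff import CAUSE, THEME, Span


class TestEventsToGraph:
    def test_three_event_example(self, fig_doc, fig_tokens):
        g = events_to_graph(fig_doc, fig_tokens)
        assert g.labels == {0: "Phosphorylation", 2: "Regulation", 3: "Binding"}
        assert g.edges == {
            (0, 1, THEME),
            (2, 3, THEME),
            (2, 0, CAUSE),
            (3, 1, THEME),
            (3, 4, THEME),
        }
        assert g.binding_pairs == {frozenset({1, 4})}

    def test_empty_document(self, fig_doc, fig_tokens):
        fig_doc.events = []
        fig_doc.triggers = []
        g = events_to_graph(fig_doc, fig_tokens)
        assert not g.labels and not g.edges and not g.binding_pairs

    def test_three_theme_binding_all_pairs(self, inv):
        # all unordered pairs of co-THEME proteins of one Binding event
        from bioevents.standoff import EventDocument, EventRecord, ProteinMention, Trigger

        text = "bnd0 PROT1 PROT2 PROT3"
        toks = [
            Token(0, "bnd0", Span(0, 4), CANDIDATE_ANCHOR),
            Token(1, "PROT1", Span(5, 10), PROTEIN, ref_id="T1"),
            Token(2, "PROT2", Span(11, 16), PROTEIN, ref_id="T2"),
            Token(3, "PROT3", Span(17, 22), PROTEIN, ref_id="T3"),
        ]
        doc = EventDocument(
            doc_id="b3",
            text=text,
            proteins=[
                ProteinMention(f"T{k}", "Protein", toks[k].span, toks[k].text)
                for k in (1, 2, 3)
            ],
            triggers=[Trigger("T4", "Binding", Span(0, 4), "bnd0")],
            events=[
                EventRecord(
                    "E1", "Binding", "T4",
                    ((THEME, "T1"), (THEME, "T2"), (THEME, "T3")),
                )
            ],
        )
        g = events_to_graph(doc, toks)
        assert g.binding_pairs == {
            frozenset(p) for p in combinations([1, 2, 3], 2)
        }


class TestGraphToEvents:
    def test_inverts_projection(self, fig_doc, fig_tokens, inv):
        g = events_to_graph(fig_doc, fig_tokens)
        doc = graph_to_events(g, inv, "fig", fig_doc.text, fig_doc.proteins)
        assert len(doc.events) == 3
        g2 = events_to_graph(doc, fig_tokens)
        assert (g2.labels, g2.edges, g2.binding_pairs) == (
            g.labels, g.edges, g.binding_pairs,
        )

    def test_unpaired_binding_themes_split(self, fig_tokens, inv):
        g = TokenGraph(
            tokens=fig_tokens,
            labels={3: "Binding"},
            edges={(3, 1, THEME), (3, 4, THEME)},
            binding_pairs=set(),
        )
        doc = graph_to_events(g, inv, "x")
        assert len(doc.events) == 2
        assert all(len(e.themes()) == 1 for e in doc.events)

    def test_full_clique_single_event(self, inv):
        toks = [
            Token(0, "bnd1", Span(0, 4), CANDIDATE_ANCHOR),
            Token(1, "PROT1", Span(5, 10), PROTEIN),
            Token(2, "PROT2", Span(11, 16), PROTEIN),
            Token(3, "PROT3", Span(17, 22), PROTEIN),
        ]
        pairs = {frozenset(p) for p in combinations([1, 2, 3], 2)}
        g = TokenGraph(
            tokens=toks,
            labels={0: "Binding"},
            edges={(0, j, THEME) for j in (1, 2, 3)},
            binding_pairs=pairs,
        )
        doc = graph_to_events(g, inv, "x")
        assert len(doc.events) == 1
        assert len(doc.events[0].themes()) == 3

    def test_constraint_violation_raises(self, fig_tokens, inv):
        g = TokenGraph(tokens=fig_tokens, labels={0: "Phosphorylation"}, edges=set())
        with pytest.raises(GraphError, match="anchor-without-theme"):
            graph_to_events(g, inv, "x")

    def test_roundtrip_on_generated_corpus(self, inv):
        corpus = synth.generate(synth.GeneratorConfig(n_docs=60, seed=21))
        for doc_id, (doc, toks) in corpus.items():
            g = events_to_graph(doc, toks)
            doc2 = graph_to_events(g, inv, doc_id, doc.text, doc.proteins)
            g2 = events_to_graph(doc2, toks)
            assert (g2.labels, g2.edges, g2.binding_pairs) == (
                g.labels, g.edges, g.binding_pairs,
            ), doc_id


def _brute_force_violations(g: TokenGraph, inv):
    """Independent checker: each constraint by explicit quantification."""
    bad = []
    # (1) every labeled anchor has >=1 outgoing THEME
    for i in g.labels:
        if not any(ii == i and r == THEME for (ii, _j, r) in g.edges):
            bad.append("c1")
    # (2) CAUSE edges only from cause-licensed labels
    for (i, j, r) in g.edges:
        if r == CAUSE and g.labels.get(i) not in inv.cause_licensed_types:
            bad.append("c2")
    # (3) anchor-kind targets must be labeled
    for (i, j, r) in g.edges:
        if g.tokens[j].kind == CANDIDATE_ANCHOR and j not in g.labels:
            bad.append("c3")
    # (4) every pair witnessed by a Binding anchor covering both
    for pair in g.binding_pairs:
        p, q = sorted(pair)
        if not any(
            g.labels.get(i) in inv.binding_types
            and (i, p, THEME) in g.edges
            and (i, q, THEME) in g.edges
            for i in g.labels
        ):
            bad.append("c4")
    return bad


class TestCheckConstraints:
    def test_example_graph_feasible(self, fig_doc, fig_tokens, inv):
        g = events_to_graph(fig_doc, fig_tokens)
        assert check_constraints(g, inv) == []

    def test_anchor_with_only_cause(self, fig_tokens, inv):
        g = TokenGraph(
            tokens=fig_tokens, labels={2: "Regulation"}, edges={(2, 1, CAUSE)}
        )
        codes = {v.code for v in check_constraints(g, inv)}
        assert "anchor-without-theme" in codes

    def test_unwitnessed_pair(self, fig_tokens, inv):
        g = TokenGraph(
            tokens=fig_tokens,
            labels={0: "Phosphorylation"},
            edges={(0, 1, THEME)},
            binding_pairs={frozenset({1, 4})},
        )
        codes = {v.code for v in check_constraints(g, inv)}
        assert "pair-unwitnessed" in codes

    def test_agrees_with_brute_force_on_random_graphs(self, tiny_inv):
        """Feasibility decisions match an exhaustive-quantification checker
        on random graphs over <=8 tokens."""
        rng = random.Random(7)
        kinds = [CANDIDATE_ANCHOR, PROTEIN, OTHER]
        for _ in range(300):
            n = rng.randint(2, 8)
            toks = [
                Token(i, f"t{i}", Span(3 * i, 3 * i + 2), rng.choice(kinds))
                for i in range(n)
            ]
            anchors = [t.index for t in toks if t.kind == CANDIDATE_ANCHOR]
            prots = [t.index for t in toks if t.kind == PROTEIN]
            labels = {
                i: rng.choice(tiny_inv.all_types)
                for i in anchors
                if rng.random() < 0.6
            }
            edges = set()
            for i in labels:
                for j in prots + [a for a in anchors if a != i]:
                    for r in (THEME, CAUSE):
                        if rng.random() < 0.25:
                            edges.add((i, j, r))
            pairs = {
                frozenset(pq)
                for pq in combinations(prots, 2)
                if rng.random() < 0.2
            }
            g = TokenGraph(tokens=toks, labels=labels, edges=edges, binding_pairs=pairs)
            ours = check_constraints(g, tiny_inv)
            brute = _brute_force_violations(g, tiny_inv)
            assert (len(ours) == 0) == (len(brute) == 0)


class TestTokenTsv:
    def test_roundtrip(self, fig_tokens):
        toks = [Token(t.index, t.text, t.span, t.kind, t.sentence) for t in fig_tokens]
        assert tokens_from_tsv(tokens_to_tsv(toks)) == toks
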