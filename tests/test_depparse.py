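"""Dependency projection, decoders, parser training, stacking protocol."""

import random
import pytest

from bioevents import synth
from bioevents.depparse import (
    ARG_ROLES,
    ROOT,
    ROOT_ROLE,
    DependencyTree,
    FoldPlan,
    TreeNode,
    decode_nonprojective,
    decode_projective,
    merge_corpora,
    parser_document,
    project_to_tree,
    stacked_predictions,
    train_parser,
    training_instance,
    tree_to_events,
)
from bioevents.graph import events_to_graph
from bioevents.matching import STRICT_POLICY, match_events_in_document, score_corpus
from bioevents.projectivity import crossing_count
from bioevents.standoff import THEME
from tests.oracles import brute_force_trees as _brute_trees
from tests.oracles import random_scored_nodes as _random_scored_nodes


class TestProjection:
    def test_single_event_two_node_tree(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=1, seed=1), inv)
        doc, toks = next(iter(corpus.values()))
        tree = project_to_tree(doc, toks)
        anchors = [n for n in tree.nodes.values() if n.event_type]
        assert anchors
        roots = [d for d, (h, _r) in tree.heads.items() if h == ROOT]
        assert roots

    def test_nonparticipants_dropped(self, fig_doc, fig_tokens):
        from bioevents.graph import OTHER, Token
        from bioevents.standoff import Span

        toks = fig_tokens + [Token(5, "filler", Span(58, 69), OTHER)]
        tree = project_to_tree(fig_doc, toks)
        assert 5 not in tree.nodes
        assert set(tree.nodes) == {0, 1, 2, 3, 4}

    def test_multiple_parents_keep_earliest_head(self, fig_doc, fig_tokens):
        # TRAF2 (token 1) has parents 0 (Phosphorylation) and 3 (Binding)
        tree = project_to_tree(fig_doc, fig_tokens)
        assert tree.heads[1] == (0, THEME)
        tree.validate()

    def test_roundtrip_tree_shaped_documents(self, inv):
        corpus = synth.generate(
            synth.GeneratorConfig(n_docs=50, seed=101, nonproj_rate=0.0), inv
        )
        for d, (doc, toks) in corpus.items():
            tree = project_to_tree(doc, toks)
            doc2 = tree_to_events(tree, inv, d, doc.text, toks, doc.proteins)
            s = score_corpus({d: doc2}, {d: doc}, STRICT_POLICY, inv)["Overall"]
            assert s.f1 == 1.0, d

    def test_anchor_with_only_cause_child_yields_no_event(self, inv):
        nodes = {
            0: TreeNode(0, "CANDIDATE_ANCHOR", "Regulation"),
            1: TreeNode(1, "PROTEIN"),
        }
        heads = {0: (ROOT, ROOT_ROLE), 1: (0, "CAUSE")}
        doc = tree_to_events(DependencyTree(nodes, heads), inv)
        assert doc.events == []


class TestDecoders:
    def test_two_nodes_agree(self):
        rng = random.Random(0)
        for _ in range(20):
            nodes, scores = _random_scored_nodes(rng, max_n=2)
            tp = decode_projective(nodes, scores)
            tn = decode_nonprojective(nodes, scores)
            assert tp.score(scores) == pytest.approx(tn.score(scores))

    def test_match_brute_force(self):
        rng = random.Random(1)
        for _ in range(60):
            nodes, scores = _random_scored_nodes(rng)
            tp = decode_projective(nodes, scores)
            tn = decode_nonprojective(nodes, scores)
            bp, _ = _brute_trees(nodes, scores, projective=True)
            bn, _ = _brute_trees(nodes, scores, projective=False)
            assert tp.score(scores) == pytest.approx(bp, abs=1e-9)
            assert tn.score(scores) == pytest.approx(bn, abs=1e-9)

    def test_projective_output_never_crosses(self):
        rng = random.Random(2)
        for _ in range(100):
            nodes, scores = _random_scored_nodes(rng, max_n=7)
            assert decode_projective(nodes, scores).crossing_count() == 0

    def test_nonprojective_dominates(self):
        rng = random.Random(3)
        for _ in range(100):
            nodes, scores = _random_scored_nodes(rng, max_n=7)
            sp = decode_projective(nodes, scores).score(scores)
            sn = decode_nonprojective(nodes, scores).score(scores)
            assert sn >= sp - 1e-9


class TestTraining:
    def test_empty_corpus_rejected(self, inv):
        with pytest.raises(ValueError, match="empty"):
            train_parser([], inv)

    def test_separable_attachment_accuracy(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=30, seed=103), inv)
        insts = [training_instance(*corpus[d]) for d in sorted(corpus)]
        model = train_parser(insts, inv, epochs=10, seed=1, decoder="1p")
        correct = total = 0
        for inst in insts:
            pred = model.decode(inst)
            for d, (h, r) in inst.gold_tree.heads.items():
                total += 1
                correct += pred.heads[d] == (h, r)
        assert correct / total == 1.0

    def test_zero_epochs_zero_weights(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=5, seed=104), inv)
        insts = [training_instance(*corpus[d]) for d in sorted(corpus)]
        model = train_parser(insts, inv, epochs=0, seed=1)
        assert model.w == {}
        # decoding still works (ties broken deterministically)
        model.decode(insts[0]).validate()

    def test_projective_gold_equal_accuracy_both_decoders(self, inv):
        corpus = synth.generate(
            synth.GeneratorConfig(n_docs=30, seed=105, nonproj_rate=0.0), inv
        )
        insts = [training_instance(*corpus[d]) for d in sorted(corpus)]
        accs = {}
        for dec in ("1p", "1n"):
            model = train_parser(insts, inv, epochs=8, seed=1, decoder=dec)
            correct = total = 0
            for inst in insts:
                pred = model.decode(inst)
                for d, hr in inst.gold_tree.heads.items():
                    total += 1
                    correct += pred.heads[d] == hr
            accs[dec] = correct / total
        assert accs["1n"] == pytest.approx(accs["1p"], abs=0.05)

    def test_nonprojective_decoder_wins_on_crossing_events(self, inv):
        """Crossing-arc gold events are recoverable by the spanning-tree
        decoder but not the projective one."""
        corpus = synth.generate(
            synth.GeneratorConfig(n_docs=80, nonproj_rate=0.5, seed=106,
                                  nonproj_pattern="interleaved"), inv
        )
        insts = {d: training_instance(*corpus[d]) for d in sorted(corpus)}
        recall = {}
        for dec in ("1p", "1n"):
            model = train_parser(list(insts.values()), inv, epochs=8, seed=1,
                                 decoder=dec)
            matched = total = 0
            for d in sorted(corpus):
                doc, toks = corpus[d]
                g = events_to_graph(doc, toks)
                if crossing_count(g) == 0:
                    continue
                tree = project_to_tree(doc, toks)
                if tree.crossing_count() == 0:
                    continue
                pred_doc = parser_document(model, insts[d], doc)
                pairs = match_events_in_document(pred_doc, doc, STRICT_POLICY)
                hit = {x for _, x in pairs if x}
                for e in doc.events:
                    total += 1
                    matched += e.id in hit
            recall[dec] = matched / total
        assert recall["1n"] > recall["1p"]


class TestStackingProtocol:
    def test_every_doc_predicted_once_never_by_own_model(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=12, seed=107), inv)
        preds = stacked_predictions(corpus, inv, n_folds=3, seed=0, epochs=2)
        assert set(preds) == set(corpus)
        plan = FoldPlan.build(list(corpus), 3, 0)
        sizes = {}
        for _d, k in plan.assignment.items():
            sizes[k] = sizes.get(k, 0) + 1
        assert max(sizes.values()) - min(sizes.values()) <= 1

    def test_leave_one_out_boundary(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=6, seed=108), inv)
        preds = stacked_predictions(corpus, inv, n_folds=6, seed=0, epochs=2)
        assert set(preds) == set(corpus)

    def test_bad_fold_counts_rejected(self, inv):
        with pytest.raises(ValueError):
            FoldPlan.build(["a", "b"], 1, 0)
        with pytest.raises(ValueError):
            FoldPlan.build(["a", "b"], 3, 0)

    def test_cross_validated_less_accurate_than_self_trained(self, inv):
        """Cross-validated stacking predictions reflect held-out accuracy;
        a model trained on everything flatters its own training data."""
        corpus = synth.generate(
            synth.GeneratorConfig(n_docs=30, seed=109, ambiguous_trigger_rate=0.5),
            inv,
        )
        gold = synth.documents(corpus)
        insts = {d: training_instance(*corpus[d]) for d in sorted(corpus)}
        full = train_parser(list(insts.values()), inv, epochs=5, seed=0)
        self_pred = {d: parser_document(full, insts[d], corpus[d][0]) for d in gold}
        cv = stacked_predictions(corpus, inv, n_folds=5, seed=0, epochs=5)
        from bioevents.depparse import tree_to_events  # noqa: F401

        f_self = score_corpus(self_pred, gold, STRICT_POLICY, inv)["Overall"].f1
        # compare anchor-label accuracy of cross-validated h maps
        correct = total = 0
        for d, sp in cv.items():
            doc, toks = corpus[d]
            g = events_to_graph(doc, toks)
            for i, t in g.labels.items():
                total += 1
                correct += sp.h.get(i) == t
        cv_anchor_acc = correct / total
        # self-trained anchor accuracy
        correct = total = 0
        for d in gold:
            doc, toks = corpus[d]
            g = events_to_graph(doc, toks)
            tree = full.decode(insts[d])
            for i, t in g.labels.items():
                total += 1
                correct += tree.nodes.get(i) is not None and tree.nodes[i].event_type == t
        self_anchor_acc = correct / total
        assert cv_anchor_acc <= self_anchor_acc
        assert f_self > 0


class TestMergeCorpora:
    def test_replication_one_is_concatenation(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=4, seed=110), inv)
        docs = synth.documents(corpus)
        merged = merge_corpora(docs, docs, 1)
        assert len(merged) == 2 * len(docs)

    def test_replication_three(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=4, seed=111), inv)
        docs = synth.documents(corpus)
        merged = merge_corpora(docs, {}, 3)
        assert len(merged) == 3 * len(docs)
        for doc_id, doc in merged.items():
            assert doc.doc_id == doc_id

    def test_invalid_replication(self, inv):
        with pytest.raises(ValueError):
            merge_corpora({}, {}, 0)
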