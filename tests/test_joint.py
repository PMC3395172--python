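"""Joint model: scoring, stacking features, dual decomposition, MIRA."""

import random
import pytest

from bioevents import synth
from bioevents.graph import (
    CANDIDATE_ANCHOR,
    PROTEIN,
    Token,
    check_constraints,
)
from bioevents.joint import (
    HEURISTIC,
    OPTIMAL,
    FeatureExtractor,
    JointAssignment,
    ScoredInstance,
    SentenceInstance,
    StackedPrediction,
    Weights,
    conjoin_features,
    gold_assignment,
    hamming_loss,
    infer_dd,
    mira_update,
    score_assignment,
    stacking_features,
    train,
)
from bioevents.matching import STRICT_POLICY
from bioevents.pipeline import predict_joint, train_joint, evaluate
from bioevents.standoff import CAUSE, THEME
from tests.oracles import brute_force_optimum, random_instance, random_scores


class TestScore:
    def test_empty_assignment_scores_zero(self, tiny_inv):
        inst = random_instance(random.Random(0), 2, 2)
        fx = FeatureExtractor(tiny_inv)
        scored = ScoredInstance(inst, fx)
        sT, sR, sB = scored.scores(Weights())
        assert score_assignment(JointAssignment.empty(), sT, sR, sB) == 0.0

    def test_sum_over_active_variables_only(self, tiny_inv):
        """Under all-ones weights on indicator features, the score equals
        the total feature count of the active variables."""
        inst = random_instance(random.Random(1), 2, 2)
        fx = FeatureExtractor(tiny_inv)
        scored = ScoredInstance(inst, fx)
        w = Weights()
        for feats in (*scored.featT.values(), *scored.featR.values(),
                      *scored.featB.values()):
            for k in feats:
                w.w[k] = 1.0
        i = inst.anchors[0]
        j = inst.proteins[0]
        y = JointAssignment(
            e=frozenset({(i, "Phosphorylation")}),
            a=frozenset({(i, j, THEME)}),
            b=frozenset(),
        )
        sT, sR, sB = scored.scores(w)
        expected = len(scored.featT[(i, "Phosphorylation")]) + len(
            scored.featR[(i, j, THEME)]
        )
        assert score_assignment(y, sT, sR, sB) == pytest.approx(expected)


class TestStackingFeatures:
    def test_matching_prediction_indicator(self):
        sp = StackedPrediction("S", h={3: "Binding"}, arcs=frozenset())
        feats = stacking_features([sp], 3, "Binding")
        assert feats == {"T|S=S|t=Binding|hS=Binding": 1.0}

    def test_disagreeing_prediction_indicator(self):
        sp = StackedPrediction("S", h={3: "Binding"}, arcs=frozenset())
        feats = stacking_features([sp], 3, "Phosphorylation")
        assert feats == {"T|S=S|t=Phosphorylation|hS=Binding": 1.0}

    def test_absent_prediction_none_bucket(self):
        sp = StackedPrediction("S", h={}, arcs=frozenset())
        feats = stacking_features([sp], 5, "Binding")
        assert feats == {"T|S=S|t=Binding|hS=NONE": 1.0}

    def test_conjoin_doubles_or_replaces(self):
        base = {"a": 1.0, "b": 2.0, "c": 1.0}
        sp = StackedPrediction("S", h={0: "Binding"}, arcs=frozenset())
        assert len(conjoin_features(base, sp, 0, keep_base=True)) == 6
        assert len(conjoin_features(base, sp, 0, keep_base=False)) == 3
        assert conjoin_features({}, sp, 0) == {}


class TestInference:
    def test_all_negative_scores_empty_optimal(self, tiny_inv):
        rng = random.Random(2)
        inst = random_instance(rng, 2, 2)
        sT, sR, sB = random_scores(rng, inst, tiny_inv.all_types, lo=-3.0, hi=-0.1)
        y, cert, info = infer_dd(inst, sT, sR, sB, tiny_inv)
        assert y == JointAssignment.empty()
        assert cert == OPTIMAL
        assert info["iterations"] == 1

    def test_certified_solutions_match_brute_force(self, tiny_inv):
        rng = random.Random(3)
        n_opt = 0
        for _ in range(150):
            inst = random_instance(rng, rng.randint(1, 3), rng.randint(1, 3))
            sT, sR, sB = random_scores(rng, inst, tiny_inv.all_types)
            y, cert, _ = infer_dd(inst, sT, sR, sB, tiny_inv)
            expect = brute_force_optimum(inst, sT, sR, sB, tiny_inv)
            got = score_assignment(y, sT, sR, sB)
            assert got <= expect + 1e-9  # never exceeds the true optimum
            if cert == OPTIMAL:
                n_opt += 1
                assert got == pytest.approx(expect, abs=1e-6)
        assert n_opt >= 100  # most small instances certify

    def test_primal_equals_dual_on_certificates(self, tiny_inv):
        rng = random.Random(4)
        for _ in range(50):
            inst = random_instance(rng, 2, 2)
            sT, sR, sB = random_scores(rng, inst, tiny_inv.all_types)
            _y, cert, info = infer_dd(inst, sT, sR, sB, tiny_inv)
            if cert == OPTIMAL:
                assert info["primal"] >= info["dual"] - 1e-9

    def test_returned_assignments_always_feasible(self, tiny_inv):
        rng = random.Random(5)
        for _ in range(100):
            inst = random_instance(rng, rng.randint(1, 4), rng.randint(0, 3))
            sT, sR, sB = random_scores(rng, inst, tiny_inv.all_types)
            y, cert, _ = infer_dd(inst, sT, sR, sB, tiny_inv, max_iter=15)
            assert cert in (OPTIMAL, HEURISTIC)
            g = y.to_graph(inst.tokens)
            assert check_constraints(g, tiny_inv) == []


class TestMira:
    def test_no_update_when_gold_equals_pred(self, tiny_inv):
        inst = random_instance(random.Random(6), 1, 1)
        scored = ScoredInstance(inst, FeatureExtractor(tiny_inv))
        w = Weights()
        y = JointAssignment.empty()
        assert mira_update(w, y, y, scored) == 0.0
        assert w.w == {}

    def test_closed_form_single_constraint(self, tiny_inv):
        """With loss 1, zero margin and a unit-norm feature difference, the
        weight moves by exactly min(C, 1.0)."""
        inst = random_instance(random.Random(7), 1, 1)
        fx = FeatureExtractor(tiny_inv)
        scored = ScoredInstance(inst, fx)
        i = inst.anchors[0]
        # collapse features to a single differing key
        key_gold = (i, "Phosphorylation")
        key_pred = (i, "Binding")
        scored.featT[key_gold] = {"only": 1.0}
        scored.featT[key_pred] = {}
        # THEME edges shared so a-features cancel
        j = inst.proteins[0]
        gold = JointAssignment(frozenset({key_gold}), frozenset({(i, j, THEME)}), frozenset())
        pred = JointAssignment(frozenset({key_pred}), frozenset({(i, j, THEME)}), frozenset())
        # hamming = 2 (two differing e-variables); ||delta||^2 = 1
        w = Weights()
        tau = mira_update(w, gold, pred, scored, C=100.0)
        assert tau == pytest.approx(2.0)  # (loss - margin)/norm2 = 2/1
        assert w.w["only"] == pytest.approx(2.0)
        # with a small C the step is clipped
        w2 = Weights()
        tau2 = mira_update(w2, gold, pred, scored, C=1.0)
        assert tau2 == pytest.approx(1.0)

    def test_zero_feature_difference_skips(self, tiny_inv):
        inst = random_instance(random.Random(8), 1, 1)
        scored = ScoredInstance(inst, FeatureExtractor(tiny_inv))
        i = inst.anchors[0]
        j = inst.proteins[0]
        scored.featT[(i, "Phosphorylation")] = {"x": 1.0}
        scored.featT[(i, "Binding")] = {"x": 1.0}
        gold = JointAssignment(frozenset({(i, "Phosphorylation")}),
                               frozenset({(i, j, THEME)}), frozenset())
        pred = JointAssignment(frozenset({(i, "Binding")}),
                               frozenset({(i, j, THEME)}), frozenset())
        w = Weights()
        assert mira_update(w, gold, pred, scored) == 0.0

    def test_hamming_loss_counts_symmetric_difference(self):
        a = JointAssignment(frozenset({(0, "X")}), frozenset({(0, 1, THEME)}), frozenset())
        b = JointAssignment(frozenset({(0, "Y")}), frozenset({(0, 1, THEME)}), frozenset())
        assert hamming_loss(a, b) == 2
        assert hamming_loss(a, a) == 0


class TestTraining:
    def test_empty_corpus_rejected(self, tiny_inv):
        with pytest.raises(ValueError, match="empty"):
            train([], None, tiny_inv)

    def test_separable_corpus_fits_training_data(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=40, seed=91), inv)
        model = train_joint(corpus, None, inv, epochs=10, seed=91, stack_mode=None)
        pred = predict_joint(model, corpus)
        s = evaluate(pred.documents, synth.documents(corpus), STRICT_POLICY, inv)
        assert s["Overall"].f1 == 1.0

    def test_training_deterministic_given_seed(self, inv):
        corpus = synth.generate(synth.separable_config(n_docs=15, seed=92), inv)
        m1 = train_joint(corpus, None, inv, epochs=3, seed=5, stack_mode=None)
        m2 = train_joint(corpus, None, inv, epochs=3, seed=5, stack_mode=None)
        assert m1.weights.averaged_view() == m2.weights.averaged_view()

    def test_predictions_satisfy_constraints(self, inv):
        corpus = synth.generate(synth.GeneratorConfig(n_docs=30, seed=93), inv)
        model = train_joint(corpus, None, inv, epochs=3, seed=93, stack_mode=None)
        pred = predict_joint(model, corpus)
        for d, g in pred.graphs.items():
            assert check_constraints(g, inv) == [], d

    def test_gold_assignment_matches_graph(self, fig_doc, fig_tokens):
        y = gold_assignment(fig_doc, fig_tokens)
        assert (2, "Regulation") in y.e
        assert (2, 0, CAUSE) in y.a
        assert frozenset({1, 4}) in y.b
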