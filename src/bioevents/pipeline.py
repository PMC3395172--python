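"""End-to-end pipelines: train/predict either extractor, evaluate, and the
canned synthetic experiments (stacking benefit, novel-event removal).

The joint model treats one document as one inference instance (synthetic
documents are single sentences by default).  Stacking input for the joint
model can come from the dependency parser's cross-validated predictions or
from any corpus in standoff form (e.g. a corrupted stand-in base model).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from . import synth
from .graph import Token, TypeInventory, ge_inventory, graph_to_events
from .joint import (
    JointModel,
    SentenceInstance,
    StackedPrediction,
    gold_assignment,
    prediction_from_document,
    train,
)
from .matching import APPROXIMATE_POLICY, STRICT_POLICY, PRF, MatchPolicy, score_corpus
from .standoff import EventDocument
from .synth import Corpus, CorruptionConfig, GeneratorConfig


def make_instances(corpus: Corpus, with_gold: bool = True) -> list[SentenceInstance]:
    out = []
    for doc_id in sorted(corpus):
        doc, tokens = corpus[doc_id]
        gold = gold_assignment(doc, tokens) if with_gold else None
        out.append(SentenceInstance(doc_id=doc_id, tokens=tokens, gold=gold))
    return out


def stacked_from_corpus(corpus: Corpus, tag: str) -> dict[str, list[StackedPrediction]]:
    return {
        doc_id: [prediction_from_document(doc, tokens, tag)]
        for doc_id, (doc, tokens) in corpus.items()
    }


def train_joint(
    corpus: Corpus,
    stacked: dict[str, list[StackedPrediction]] | None = None,
    inventory: TypeInventory | None = None,
    epochs: int = 10,
    C: float = 0.1,
    seed: int = 0,
    stack_mode: str | None = "both",
    conjoin: bool = False,
) -> JointModel:
    inv = inventory or ge_inventory()
    instances = make_instances(corpus)
    return train(
        instances, stacked, inv, epochs=epochs, C=C, seed=seed,
        stack_mode=stack_mode, conjoin=conjoin,
    )


@dataclass
class JointPrediction:
    documents: dict[str, EventDocument]
    graphs: dict
    certificates: dict[str, str]


def predict_joint(
    model: JointModel,
    corpus: Corpus,
    stacked: dict[str, list[StackedPrediction]] | None = None,
) -> JointPrediction:
    docs: dict[str, EventDocument] = {}
    graphs = {}
    certs: dict[str, str] = {}
    inv = model.fx.inventory
    for doc_id in sorted(corpus):
        doc, tokens = corpus[doc_id]
        inst = SentenceInstance(doc_id=doc_id, tokens=tokens)
        preds = (stacked or {}).get(doc_id)
        y, cert, _info = model.predict(inst, stacked=preds if stacked is not None else None)
        g = y.to_graph(tokens)
        graphs[doc_id] = g
        certs[doc_id] = cert
        docs[doc_id] = graph_to_events(
            g, inv, doc_id=doc_id, text=doc.text, proteins=doc.proteins
        )
    return JointPrediction(documents=docs, graphs=graphs, certificates=certs)


def evaluate(
    pred: dict[str, EventDocument],
    gold: dict[str, EventDocument],
    policy: MatchPolicy = APPROXIMATE_POLICY,
    inventory: TypeInventory | None = None,
) -> dict[str, PRF]:
    return score_corpus(pred, gold, policy, inventory or ge_inventory())


# ---------------------------------------------------------------------------
# canned experiments


#: corruption applied to gold to obtain the stand-in base-model output used
#: as stacking input: a strong but imperfect system
BASE_MODEL_CORRUPTION = dict(anchor_miss=0.15, type_confusion=0.10, arc_miss=0.10)


def stacking_experiment(
    seed: int,
    n_docs: int = 500,
    n_train: int = 350,
    epochs: int = 3,
    inventory: TypeInventory | None = None,
) -> dict[str, float]:
    """Train the joint model with and without stacking input on one
    synthetic corpus and report dev F1 for both.

    The corpus carries ambiguous trigger words (their surface form does not
    reveal the event type), so the corrupted base-model predictions carry
    signal the joint model's own features cannot recover — the conditions
    under which stacking should help.
    """
    inv = inventory or ge_inventory()
    cfg = GeneratorConfig(n_docs=n_docs, seed=seed)
    corpus = synth.generate(cfg, inv)
    base = synth.corrupt(
        corpus, CorruptionConfig(**BASE_MODEL_CORRUPTION, seed=seed + 10_000), inv
    )
    stacked = stacked_from_corpus(base, tag="base")

    ids = sorted(corpus)
    train_ids, dev_ids = ids[:n_train], ids[n_train:]
    train_corpus = {d: corpus[d] for d in train_ids}
    dev_corpus = {d: corpus[d] for d in dev_ids}
    dev_gold = synth.documents(dev_corpus)

    out: dict[str, float] = {}
    for label, stack in (("alone", None), ("stacked", stacked)):
        model = train_joint(
            train_corpus,
            stacked={d: stack[d] for d in train_ids} if stack else None,
            inventory=inv, epochs=epochs, seed=seed,
            stack_mode="both" if stack else None,
        )
        pred = predict_joint(
            model, dev_corpus,
            stacked={d: stack[d] for d in dev_ids} if stack else None,
        )
        prf = evaluate(pred.documents, dev_gold, APPROXIMATE_POLICY, inv)["Overall"]
        out[f"f1_{label}"] = prf.f1
        out[f"precision_{label}"] = prf.precision
        out[f"recall_{label}"] = prf.recall
    out["f1_gain"] = out["f1_stacked"] - out["f1_alone"]
    return out


def stacking_sign_test(
    n_seeds: int = 10, base_seed: int = 0, **kwargs
) -> dict[str, float]:
    """Paired comparison of stacked vs standalone dev F1 over seeds, with a
    one-sided sign test on the wins."""
    gains = []
    f1_alone = []
    f1_stacked = []
    for k in range(n_seeds):
        res = stacking_experiment(seed=base_seed + 101 * k + 1, **kwargs)
        gains.append(res["f1_gain"])
        f1_alone.append(res["f1_alone"])
        f1_stacked.append(res["f1_stacked"])
    wins = sum(1 for g in gains if g > 0)
    ties = sum(1 for g in gains if g == 0)
    n_eff = len(gains) - ties
    p = binomtest(wins, n_eff, 0.5, alternative="greater").pvalue if n_eff else 1.0
    med = sorted(f1_alone)[len(f1_alone) // 2], sorted(f1_stacked)[len(f1_stacked) // 2]
    return {
        "median_f1_alone": med[0],
        "median_f1_stacked": med[1],
        "wins": wins,
        "n_seeds": n_seeds,
        "p_value": float(p),
    }


def novel_removal_experiment(seed: int, n_docs: int = 60) -> dict[str, float]:
    """Planted-correctness check of novel-event filtering.

    Gold is generated; two corrupted copies play the standalone base
    models; the combined output is their union plus planted spurious
    events (novel by construction, wrong by construction).  Removing NOVEL
    events must raise precision and cannot raise recall.
    """
    from .combine import remove_novel

    inv = ge_inventory()
    cfg = GeneratorConfig(n_docs=n_docs, seed=seed)
    corpus = synth.generate(cfg, inv)
    gold_docs = synth.documents(corpus)
    light = dict(anchor_miss=0.1, type_confusion=0.05, arc_miss=0.05)
    base_a = synth.corrupt(corpus, CorruptionConfig(**light, seed=seed + 1), inv)
    base_b = synth.corrupt(corpus, CorruptionConfig(**light, seed=seed + 2), inv)

    from .combine import combine_union

    union = combine_union(synth.documents(base_a), synth.documents(base_b), STRICT_POLICY)
    with_novel = synth.inject_spurious(
        {d: (union[d], corpus[d][1]) for d in union}, rate=0.7, seed=seed + 3, inventory=inv
    )
    final = synth.documents(with_novel)

    filtered = remove_novel(
        final, synth.documents(base_a), synth.documents(base_b), STRICT_POLICY
    )
    before = score_corpus(final, gold_docs, STRICT_POLICY, inv)["Overall"]
    after = score_corpus(filtered, gold_docs, STRICT_POLICY, inv)["Overall"]
    return {
        "precision_before": before.precision,
        "precision_after": after.precision,
        "recall_before": before.recall,
        "recall_after": after.recall,
        "precision_gain": after.precision - before.precision,
        "recall_drop": before.recall - after.recall,
    }
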