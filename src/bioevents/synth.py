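"""Synthetic standoff corpora with controllable structural statistics.

Documents are synthetic token strings (``PROT17``, ``pho3``, filler words)
joined by single spaces, so character-offset arithmetic is exercised
without any linguistic preprocessing; every document ships with a token
sidecar marking protein tokens and candidate anchors.  The generator
controls the event-type mix, regulation nesting, the multi-THEME rate of
Binding events, trigger-word ambiguity (whether the anchor's surface form
reveals its event type) and the fraction of documents containing a
non-projective (crossing-arc) construction — the canonical pattern being a
Regulation whose CAUSE arc interleaves with a Binding THEME arc.

A corruption model derives "base-model output" corpora of controlled
quality from gold: events are dropped (anchor misses), retyped (type
confusion), their arcs dropped/added and trigger spans jittered.  These
corrupted corpora stand in for the predictions of real base extractors
when testing stacking and combination.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field, replace

from .graph import (
    CANDIDATE_ANCHOR,
    OTHER,
    PROTEIN,
    Token,
    TypeInventory,
    ge_inventory,
    tokens_to_tsv,
)
from .standoff import (
    CAUSE,
    THEME,
    EventDocument,
    EventRecord,
    ProteinMention,
    Span,
    Trigger,
    topological_events,
    write_document,
)

TYPE_PREFIX = {
    "Gene_expression": "gex",
    "Transcription": "txn",
    "Localization": "loc",
    "Catabolism": "cat",
    "Phosphorylation": "pho",
    "Binding": "bnd",
    "Regulation": "reg",
    "Positive_regulation": "pos",
    "Negative_regulation": "neg",
    "Methylation": "met",
    "Acetylation": "ace",
    "Ubiquitination": "ubi",
    "Glycosylation": "gly",
    "Catalysis": "cly",
    "Process": "prc",
}

#: default event-type mix, loosely following the Genia skew (expression
#: events frequent, catabolism rare)
DEFAULT_TYPE_DIST = {
    "Gene_expression": 0.20,
    "Phosphorylation": 0.12,
    "Transcription": 0.08,
    "Localization": 0.08,
    "Catabolism": 0.07,
    "Binding": 0.20,
    "Regulation": 0.10,
    "Positive_regulation": 0.08,
    "Negative_regulation": 0.07,
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 100
    n_sentences: int = 1
    max_events_per_sentence: int = 3
    type_dist: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_DIST),
                            hash=False, compare=False)
    nesting_prob: float = 0.3       # Regulation THEME is itself an event
    multi_theme_prob: float = 0.5   # Binding takes two THEMEs
    cause_prob: float = 0.4         # Regulation carries a CAUSE protein
    nonproj_rate: float = 0.2       # documents containing a crossing arc
    #: crossing construction: "regulation-cause" (a Regulation's CAUSE arc
    #: interleaves a Binding THEME arc; the crossing involves a shared
    #: argument and does not survive tree projection), "interleaved" (two
    #: simple events with swapped THEME order; survives projection) or
    #: "mixed" (either, at random)
    nonproj_pattern: str = "mixed"
    ambiguous_trigger_rate: float = 0.35  # trigger word does not reveal type
    distractor_protein_rate: float = 0.6  # extra protein mention per sentence
    distractor_anchor_rate: float = 0.4   # inactive anchor candidate per sentence
    trigger_vocab: int = 8
    protein_vocab: int = 40
    filler_vocab: int = 25
    seed: int = 0

    def validate(self) -> None:
        for name in ("nesting_prob", "multi_theme_prob", "cause_prob", "nonproj_rate",
                     "ambiguous_trigger_rate", "distractor_protein_rate",
                     "distractor_anchor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if self.nonproj_rate > 0 and self.max_events_per_sentence < 1:
            raise ConfigError("non-projectivity injection needs at least one event slot")
        if abs(sum(self.type_dist.values()) - 1.0) > 1e-6:
            raise ConfigError("type_dist must sum to 1")
        if self.nonproj_pattern not in ("regulation-cause", "interleaved", "mixed"):
            raise ConfigError(f"unknown nonproj_pattern {self.nonproj_pattern!r}")


def separable_config(n_docs: int = 60, seed: int = 0) -> GeneratorConfig:
    """Conditions under which the extraction task is linearly separable:
    unambiguous type-revealing trigger words, fixed argument layout, no
    crossing arcs."""
    return GeneratorConfig(
        n_docs=n_docs,
        nonproj_rate=0.0,
        ambiguous_trigger_rate=0.0,
        nesting_prob=0.0,
        cause_prob=0.0,
        multi_theme_prob=1.0,
        distractor_anchor_rate=0.0,
        seed=seed,
    )


@dataclass(frozen=True)
class CorruptionConfig:
    anchor_miss: float = 0.0
    type_confusion: float | dict = 0.0  # rate (within valence class) or matrix
    arc_miss: float = 0.0
    arc_add: float = 0.0
    span_jitter: int = 0  # widen trigger spans by up to this many tokens
    seed: int = 0


Corpus = dict[str, tuple[EventDocument, list[Token]]]


class _SentenceBuilder:
    def __init__(self, rng: random.Random, cfg: GeneratorConfig, inv: TypeInventory,
                 sentence: int) -> None:
        self.rng = rng
        self.cfg = cfg
        self.inv = inv
        self.sentence = sentence
        self.words: list[tuple[str, str]] = []  # (text, kind)
        self.events: list[dict] = []  # {"type", "anchor", "args": [(role, tgt)]}
        # targets are ("P", word_pos) for proteins or ("E", event_index)

    # -- vocabulary ---------------------------------------------------------
    def _protein_word(self) -> str:
        return f"PROT{self.rng.randrange(self.cfg.protein_vocab)}"

    def _filler(self) -> str:
        return f"w{self.rng.randrange(self.cfg.filler_vocab)}"

    def _trigger_word(self, etype: str) -> str:
        k = self.rng.randrange(self.cfg.trigger_vocab)
        if self.rng.random() < self.cfg.ambiguous_trigger_rate:
            return f"amb{k}"
        return f"{TYPE_PREFIX[etype]}{k}"

    def _add(self, text: str, kind: str) -> int:
        self.words.append((text, kind))
        return len(self.words) - 1

    def _sample_type(self, classes: set[str] | None = None) -> str:
        dist = self.cfg.type_dist
        items = [
            (t, p) for t, p in sorted(dist.items()) if classes is None or t in classes
        ]
        total = sum(p for _, p in items)
        x = self.rng.random() * total
        for t, p in items:
            x -= p
            if x <= 0:
                return t
        return items[-1][0]

    # -- event groups ---------------------------------------------------------
    def add_fillers(self, lo: int = 0, hi: int = 2) -> None:
        for _ in range(self.rng.randint(lo, hi)):
            self._add(self._filler(), OTHER)

    def add_distractors(self) -> None:
        if self.rng.random() < self.cfg.distractor_protein_rate:
            self._add(self._protein_word(), PROTEIN)
        if self.rng.random() < self.cfg.distractor_anchor_rate:
            etype = self._sample_type()
            self._add(self._trigger_word(etype), CANDIDATE_ANCHOR)

    def add_event_group(self, etype: str | None = None, allow_nesting: bool = True) -> int:
        """Append one event's tokens and record; returns the event index."""
        inv = self.inv
        if etype is None:
            etype = self._sample_type()
        anchor = self._add(self._trigger_word(etype), CANDIDATE_ANCHOR)
        args: list[tuple[str, tuple]] = []
        if etype in inv.binding_types:
            p1 = self._add(self._protein_word(), PROTEIN)
            args.append((THEME, ("P", p1)))
            if self.rng.random() < self.cfg.multi_theme_prob:
                p2 = self._add(self._protein_word(), PROTEIN)
                args.append((THEME, ("P", p2)))
        elif etype in inv.regulation_types:
            if allow_nesting and self.rng.random() < self.cfg.nesting_prob:
                sub_type = self._sample_type(inv.simple_types | inv.binding_types)
                sub = self.add_event_group(sub_type, allow_nesting=False)
                args.append((THEME, ("E", sub)))
            else:
                p = self._add(self._protein_word(), PROTEIN)
                args.append((THEME, ("P", p)))
            if self.rng.random() < self.cfg.cause_prob:
                c = self._add(self._protein_word(), PROTEIN)
                args.append((CAUSE, ("P", c)))
        else:  # simple event: exactly one protein THEME right after the anchor
            p = self._add(self._protein_word(), PROTEIN)
            args.append((THEME, ("P", p)))
        self.events.append({"type": etype, "anchor": anchor, "args": args})
        return len(self.events) - 1

    def add_nonprojective_group(self) -> None:
        """The canonical crossing construction: a Regulation whose CAUSE arc
        back to a simple event interleaves with a Binding THEME arc
        (anchor order: simple, P1, regulation, binding, P2)."""
        inv = self.inv
        simple_type = self._sample_type(inv.simple_types)
        reg_type = self._sample_type(inv.regulation_types)
        bind_types = sorted(inv.binding_types)
        if not bind_types:
            raise ConfigError("non-projectivity injection needs a binding type")
        bind_type = bind_types[0]
        a_simple = self._add(self._trigger_word(simple_type), CANDIDATE_ANCHOR)
        p1 = self._add(self._protein_word(), PROTEIN)
        a_reg = self._add(self._trigger_word(reg_type), CANDIDATE_ANCHOR)
        a_bind = self._add(self._trigger_word(bind_type), CANDIDATE_ANCHOR)
        p2 = self._add(self._protein_word(), PROTEIN)
        self.events.append({"type": simple_type, "anchor": a_simple,
                            "args": [(THEME, ("P", p1))]})
        e_simple = len(self.events) - 1
        self.events.append({"type": bind_type, "anchor": a_bind,
                            "args": [(THEME, ("P", p1)), (THEME, ("P", p2))]})
        e_bind = len(self.events) - 1
        self.events.append({"type": reg_type, "anchor": a_reg,
                            "args": [(THEME, ("E", e_bind)), (CAUSE, ("E", e_simple))]})

    def add_interleaved_group(self) -> None:
        """Two simple events with interleaved THEME arcs (anchor order
        A, P1, P2, B with A -> P2 and B -> P1): a crossing that also
        survives projection to the dependency-tree representation."""
        t_a = self._sample_type(self.inv.simple_types)
        t_b = self._sample_type(self.inv.simple_types)
        a = self._add(self._trigger_word(t_a), CANDIDATE_ANCHOR)
        p1 = self._add(self._protein_word(), PROTEIN)
        p2 = self._add(self._protein_word(), PROTEIN)
        b = self._add(self._trigger_word(t_b), CANDIDATE_ANCHOR)
        self.events.append({"type": t_a, "anchor": a, "args": [(THEME, ("P", p2))]})
        self.events.append({"type": t_b, "anchor": b, "args": [(THEME, ("P", p1))]})

    def add_crossing_group(self) -> None:
        pat = self.cfg.nonproj_pattern
        if pat == "mixed":
            pat = "regulation-cause" if self.rng.random() < 0.5 else "interleaved"
        if pat == "regulation-cause":
            self.add_nonprojective_group()
        else:
            self.add_interleaved_group()


def _build_document(
    doc_id: str, rng: random.Random, cfg: GeneratorConfig, inv: TypeInventory
) -> tuple[EventDocument, list[Token]]:
    all_words: list[tuple[str, str, int]] = []
    sentence_events: list[tuple[int, list[dict], int]] = []  # (offset, events, sent)
    inject_doc = rng.random() < cfg.nonproj_rate
    inject_sentence = rng.randrange(cfg.n_sentences) if inject_doc else -1
    for s in range(cfg.n_sentences):
        sb = _SentenceBuilder(rng, cfg, inv, s)
        sb.add_fillers(0, 2)
        n_events = rng.randint(1, cfg.max_events_per_sentence)
        injected = False
        for k in range(n_events):
            if s == inject_sentence and not injected:
                sb.add_crossing_group()
                injected = True
            else:
                sb.add_event_group()
            sb.add_fillers(1, 2)
            if k == 0:
                sb.add_distractors()
        offset = len(all_words)
        all_words.extend((w, kind, s) for (w, kind) in sb.words)
        sentence_events.append((offset, sb.events, s))

    # realize text, spans, tokens
    tokens: list[Token] = []
    pos = 0
    parts: list[str] = []
    for idx, (w, kind, s) in enumerate(all_words):
        span = Span(pos, pos + len(w))
        tokens.append(Token(idx, w, span, kind, s))
        parts.append(w)
        pos += len(w) + 1
    text = " ".join(parts)

    doc = EventDocument(doc_id=doc_id, text=text)
    pnum = 0
    prot_ids: dict[int, str] = {}
    for t in tokens:
        if t.kind == PROTEIN:
            pnum += 1
            pid = f"T{pnum}"
            prot_ids[t.index] = pid
            doc.proteins.append(ProteinMention(pid, "Protein", t.span, t.text))
    tokens = [
        replace(t, ref_id=prot_ids.get(t.index)) for t in tokens
    ]

    tnum = pnum
    enum = 0
    for offset, events, _s in sentence_events:
        eids: dict[int, str] = {}
        order = sorted(
            range(len(events)),
            key=lambda k: 0 if all(tgt[0] == "P" for _, tgt in events[k]["args"]) else 1,
        )
        for k in order:
            ev = events[k]
            anchor_tok = tokens[offset + ev["anchor"]]
            tnum += 1
            enum += 1
            tid = f"T{tnum}"
            eid = f"E{enum}"
            eids[k] = eid
            doc.triggers.append(
                Trigger(tid, ev["type"], anchor_tok.span, anchor_tok.text)
            )
            args = []
            for role, (sort, ref) in ev["args"]:
                if sort == "P":
                    args.append((role, prot_ids[offset + ref]))
                else:
                    args.append((role, eids[ref]))
            doc.events.append(EventRecord(eid, ev["type"], tid, tuple(args)))
    doc.validate()
    return doc, tokens


def generate(config: GeneratorConfig, inventory: TypeInventory | None = None) -> Corpus:
    """Generate a corpus of validated standoff documents with token sidecars.

    Deterministic given ``config.seed``; the realized fraction of documents
    containing a crossing arc concentrates around ``nonproj_rate``.
    """
    config.validate()
    inv = inventory or ge_inventory()
    for t in config.type_dist:
        if t not in inv.all_types:
            raise ConfigError(f"type {t} not in inventory")
    rng = random.Random(config.seed)
    corpus: Corpus = {}
    width = max(4, len(str(config.n_docs)))
    for n in range(config.n_docs):
        doc_id = f"SYN{n:0{width}d}"
        corpus[doc_id] = _build_document(doc_id, rng, config, inv)
    return corpus


def documents(corpus: Corpus) -> dict[str, EventDocument]:
    return {k: doc for k, (doc, _toks) in corpus.items()}


def tokens_map(corpus: Corpus) -> dict[str, list[Token]]:
    return {k: toks for k, (_doc, toks) in corpus.items()}


def read_corpus_with_tokens(directory: str) -> Corpus:
    """Read a directory of standoff triples plus ``.tokens.tsv`` sidecars."""
    from .graph import tokens_from_tsv
    from .standoff import read_corpus

    docs = read_corpus(directory)
    out: Corpus = {}
    for doc_id, doc in docs.items():
        path = os.path.join(directory, doc_id + ".tokens.tsv")
        with open(path, encoding="utf-8") as fh:
            toks = tokens_from_tsv(fh.read())
        # re-attach protein ids to protein tokens
        by_span = {p.span: p.id for p in doc.proteins}
        toks = [replace(t, ref_id=by_span.get(t.span)) for t in toks]
        out[doc_id] = (doc, toks)
    return out


def write_synthetic_corpus(corpus: Corpus, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    for doc_id, (doc, tokens) in corpus.items():
        a1, a2 = write_document(doc)
        for ext, content in (
            (".txt", doc.text), (".a1", a1), (".a2", a2),
            (".tokens.tsv", tokens_to_tsv(tokens)),
        ):
            with open(os.path.join(directory, doc_id + ext), "w", encoding="utf-8") as fh:
                fh.write(content)


# ---------------------------------------------------------------------------
# corruption: derive base-model-like predictions of controlled quality


def _confusion_target(
    etype: str, inv: TypeInventory, spec: float | dict, rng: random.Random
) -> str:
    if isinstance(spec, dict):
        row = spec.get(etype)
        if not row:
            return etype
        x = rng.random()
        for t, p in sorted(row.items()):
            x -= p
            if x <= 0:
                return t
        return etype
    if spec <= 0 or rng.random() >= spec:
        return etype
    if etype in inv.simple_types:
        pool = sorted(inv.simple_types - {etype})
    elif etype in inv.regulation_types:
        pool = sorted(inv.regulation_types - {etype})
    else:
        pool = []
    return rng.choice(pool) if pool else etype


def corrupt(gold: Corpus, config: CorruptionConfig,
            inventory: TypeInventory | None = None) -> Corpus:
    """Derive a degraded copy of a gold corpus (a stand-in base model).

    Event-level anchor misses remove whole events (parents that referenced
    them cascade away); type confusion relabels events within their valence
    class; arc misses drop arguments (an event losing all THEMEs is
    dropped); arc adds attach a spurious argument compatible with the
    event's valence; span jitter widens trigger spans by whole tokens.
    Output documents are valid standoff.
    """
    inv = inventory or ge_inventory()
    rng = random.Random(config.seed)
    out: Corpus = {}
    for doc_id in sorted(gold):
        doc, tokens = gold[doc_id]
        prot_tokens = [t for t in tokens if t.kind == PROTEIN]
        new = EventDocument(doc_id=doc_id, text=doc.text)
        new.proteins = list(doc.proteins)
        triggers = doc.trigger_by_id()
        kept: dict[str, EventRecord] = {}
        tnum = 5000
        enum = 0
        for ev in topological_events(doc):
            if rng.random() < config.anchor_miss:
                continue
            etype = _confusion_target(ev.event_type, inv, config.type_confusion, rng)
            args: list[tuple[str, str]] = []
            for role, target in ev.args:
                if target in doc.event_by_id():
                    if target not in kept:
                        continue  # nested event vanished
                    ref = kept[target].id
                else:
                    ref = target
                if rng.random() < config.arc_miss:
                    continue
                args.append((role, ref))
            if not any(r == THEME for r, _ in args):
                continue  # no THEME left: the event cannot stand
            if config.arc_add > 0 and rng.random() < config.arc_add and prot_tokens:
                pick = rng.choice(prot_tokens).ref_id
                if etype in inv.binding_types:
                    if all(t != pick for _, t in args):
                        args.append((THEME, pick))
                elif etype in inv.cause_licensed_types:
                    if not any(r == CAUSE for r, _ in args):
                        args.append((CAUSE, pick))
                else:  # simple events: substitute the THEME target
                    args = [(THEME, pick)] + [a for a in args if a[0] != THEME][:0]
            # regulation/simple valence: at most one THEME survives corruption
            if etype not in inv.binding_types:
                themes = [a for a in args if a[0] == THEME][:1]
                causes = [a for a in args if a[0] == CAUSE]
                causes = causes[:1] if etype in inv.cause_licensed_types else []
                args = themes + causes
            trg = triggers[ev.trigger_id]
            span = trg.span
            if config.span_jitter > 0 and rng.random() < 0.5:
                span = _widen_span(span, tokens, config.span_jitter, doc.text)
            tnum += 1
            enum += 1
            trig = Trigger(f"T{tnum}", etype, span, doc.text[span.start:span.end])
            new.triggers.append(trig)
            rec = EventRecord(f"E{enum}", etype, trig.id, tuple(args))
            new.events.append(rec)
            kept[ev.id] = rec
        new.validate()
        out[doc_id] = (new, tokens)
    return out


def _widen_span(span: Span, tokens: list[Token], jitter: int, text: str) -> Span:
    following = [t for t in tokens if t.span.start >= span.end]
    following.sort(key=lambda t: t.span.start)
    if not following:
        return span
    take = following[: max(1, jitter)][-1] if jitter > 1 else following[0]
    return Span(span.start, take.span.end)


def inject_spurious(
    corpus: Corpus, rate: float, seed: int, inventory: TypeInventory | None = None
) -> Corpus:
    """Plant wrong events at unused candidate-anchor tokens (synthetic
    "novel" events that no base model proposed and that never match gold).
    """
    inv = inventory or ge_inventory()
    rng = random.Random(seed)
    out: Corpus = {}
    simple = sorted(inv.simple_types)
    for doc_id in sorted(corpus):
        doc, tokens = corpus[doc_id]
        used_spans = {t.span for t in doc.triggers}
        free_anchors = [
            t for t in tokens if t.kind == CANDIDATE_ANCHOR and t.span not in used_spans
        ]
        prots = [t for t in tokens if t.kind == PROTEIN and t.ref_id]
        new = EventDocument(doc_id=doc_id, text=doc.text)
        new.proteins = list(doc.proteins)
        new.triggers = list(doc.triggers)
        new.events = list(doc.events)
        n = 9000
        for tok in free_anchors:
            if not prots or rng.random() >= rate:
                continue
            n += 1
            etype = rng.choice(simple)
            trig = Trigger(f"T{n}", etype, tok.span, tok.text)
            new.triggers.append(trig)
            new.events.append(
                EventRecord(f"E{n}", etype, trig.id,
                            ((THEME, rng.choice(prots).ref_id),))
            )
        new.validate()
        out[doc_id] = (new, tokens)
    return out


def expected_strict_recall_under_arc_miss(corpus: Corpus, arc_miss: float) -> float:
    """Analytic expectation of strict recall when only arcs are dropped:
    an event survives intact iff every argument arc in its recursive
    closure is kept."""
    probs: list[float] = []
    for doc_id in sorted(corpus):
        doc, _tokens = corpus[doc_id]
        events = doc.event_by_id()

        def intact(eid: str) -> float:
            e = events[eid]
            p = (1.0 - arc_miss) ** len(e.args)
            for _role, target in e.args:
                if target in events:
                    p *= intact(target)
            return p

        for e in doc.events:
            probs.append(intact(e.id))
    return sum(probs) / len(probs) if probs else 0.0
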