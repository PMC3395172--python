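"""Event equality and precision/recall/F1 scoring.

Two policies mirror the shared task's scoring modes:

* STRICT ("non-approximate recursive"): trigger spans must be identical and
  nested event arguments are compared on their full argument sets,
  recursively.
* APPROXIMATE ("approximate recursive"): a predicted trigger span may
  deviate from gold by up to ``span_slack`` tokens (it must lie within the
  gold span extended by that many words on either side), and nested event
  arguments are compared on their core only — type, trigger and THEME
  arguments.

Protein targets are compared by surface identity (entity type and span);
the given .a1 entities are shared between gold and predictions, so this is
exact.  Duplicate THEME targets are collapsed (compared as sets).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .graph import TypeInventory
from .standoff import CAUSE, THEME, EventDocument, EventRecord, Span

STRICT = "STRICT"
APPROXIMATE = "APPROXIMATE"


@dataclass(frozen=True)
class MatchPolicy:
    span_slack: int = 0
    recursive_mode: str = STRICT

    def __post_init__(self) -> None:
        if self.span_slack < 0:
            raise ValueError("span_slack must be >= 0")
        if self.recursive_mode not in (STRICT, APPROXIMATE):
            raise ValueError(f"unknown recursive_mode {self.recursive_mode!r}")


STRICT_POLICY = MatchPolicy(span_slack=0, recursive_mode=STRICT)
APPROXIMATE_POLICY = MatchPolicy(span_slack=1, recursive_mode=APPROXIMATE)


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


_WORD_RE = re.compile(r"\S+")


def _extend_span(span: Span, text: str, slack: int) -> Span:
    """Extend a span by ``slack`` whitespace-delimited words on each side."""
    if slack == 0:
        return span
    words = [(m.start(), m.end()) for m in _WORD_RE.finditer(text)]
    starts = [s for (s, e) in words if e <= span.start]
    start = starts[-slack] if len(starts) >= slack else (starts[0] if starts else span.start)
    ends = [e for (s, e) in words if s >= span.end]
    end = ends[slack - 1] if len(ends) >= slack else (ends[-1] if ends else span.end)
    return Span(min(start, span.start), max(end, span.end))


def spans_match(pred: Span, gold: Span, gold_text: str, slack: int) -> bool:
    if slack == 0:
        return pred == gold
    ext = _extend_span(gold, gold_text, slack)
    return ext.start <= pred.start and pred.end <= ext.end


def events_match(
    pred: EventRecord,
    gold: EventRecord,
    policy: MatchPolicy,
    pred_doc: EventDocument,
    gold_doc: EventDocument,
    _nested: bool = False,
) -> bool:
    """Recursive event equality under the given policy."""
    if pred.event_type != gold.event_type:
        return False
    pt = pred_doc.trigger_by_id()[pred.trigger_id]
    gt = gold_doc.trigger_by_id()[gold.trigger_id]
    if not spans_match(pt.span, gt.span, gold_doc.text, policy.span_slack):
        return False
    core_only = _nested and policy.recursive_mode == APPROXIMATE
    roles = [THEME] if core_only else [THEME, CAUSE]
    for role in roles:
        if not _role_args_match(pred, gold, role, policy, pred_doc, gold_doc):
            return False
    return True


def _role_args_match(
    pred: EventRecord,
    gold: EventRecord,
    role: str,
    policy: MatchPolicy,
    pred_doc: EventDocument,
    gold_doc: EventDocument,
) -> bool:
    p_prot, p_evt = _split_targets(pred, role, pred_doc)
    g_prot, g_evt = _split_targets(gold, role, gold_doc)
    if p_prot != g_prot:
        return False
    if len(p_evt) != len(g_evt):
        return False
    return _event_bijection(p_evt, g_evt, policy, pred_doc, gold_doc)


def _split_targets(
    e: EventRecord, role: str, doc: EventDocument
) -> tuple[set[tuple[str, int, int]], list[EventRecord]]:
    """Role targets split into protein surface keys and event records.

    Duplicate protein targets collapse (set semantics); event targets keep
    multiplicity.
    """
    prots: set[tuple[str, int, int]] = set()
    evts: list[EventRecord] = []
    proteins = doc.protein_by_id()
    events = doc.event_by_id()
    for r, target in e.args:
        if r != role:
            continue
        if target in proteins:
            p = proteins[target]
            prots.add((p.type, p.span.start, p.span.end))
        else:
            evts.append(events[target])
    return prots, evts


def _event_bijection(
    pred_events: list[EventRecord],
    gold_events: list[EventRecord],
    policy: MatchPolicy,
    pred_doc: EventDocument,
    gold_doc: EventDocument,
) -> bool:
    """Perfect matching between nested pred/gold event arguments
    (backtracking search; argument counts are tiny in practice)."""
    if not pred_events:
        return not gold_events
    used = [False] * len(gold_events)

    def backtrack(k: int) -> bool:
        if k == len(pred_events):
            return True
        for m, g in enumerate(gold_events):
            if used[m]:
                continue
            if events_match(pred_events[k], g, policy, pred_doc, gold_doc, _nested=True):
                used[m] = True
                if backtrack(k + 1):
                    return True
                used[m] = False
        return False

    return backtrack(0)


def match_events_in_document(
    pred_doc: EventDocument | None,
    gold_doc: EventDocument,
    policy: MatchPolicy,
) -> list[tuple[str, str | None]]:
    """Greedy one-to-one matching: predictions in serialization order, each
    taking the first unconsumed matching gold event.  Returns
    ``(pred_event_id, matched_gold_id_or_None)`` pairs."""
    out: list[tuple[str, str | None]] = []
    if pred_doc is None:
        return out
    consumed: set[str] = set()
    for pe in pred_doc.events:
        hit: str | None = None
        for ge in gold_doc.events:
            if ge.id in consumed:
                continue
            if events_match(pe, ge, policy, pred_doc, gold_doc):
                hit = ge.id
                consumed.add(ge.id)
                break
        out.append((pe.id, hit))
    return out


def matched_event_count(
    pred_doc: EventDocument | None, gold_doc: EventDocument, policy: MatchPolicy
) -> int:
    return sum(1 for _, g in match_events_in_document(pred_doc, gold_doc, policy) if g)


def score_corpus(
    pred: dict[str, EventDocument],
    gold: dict[str, EventDocument],
    policy: MatchPolicy,
    inventory: TypeInventory | None = None,
) -> dict[str, PRF]:
    """Micro-averaged PRF, overall and per event category.

    Events are matched greedily one-to-one per document; the category of an
    event is the class of its type in the inventory (Simple / Binding /
    Regulation).  Returns a dict keyed by category plus ``"Overall"``.
    """
    if set(pred) - set(gold):
        raise KeyError(f"prediction doc_ids not in gold: {sorted(set(pred) - set(gold))}")
    counts: dict[str, dict[str, int]] = {}

    def bump(cat: str, key: str) -> None:
        counts.setdefault(cat, {"tp": 0, "fp": 0, "fn": 0})[key] += 1

    for doc_id in sorted(gold):
        gold_doc = gold[doc_id]
        pred_doc = pred.get(doc_id)
        pairs = match_events_in_document(pred_doc, gold_doc, policy)
        matched_gold = {g for _, g in pairs if g}
        if pred_doc is not None:
            events = pred_doc.event_by_id()
            for pid, gid in pairs:
                cat = inventory.category(events[pid].event_type) if inventory else "Overall"
                bump("Overall", "tp" if gid else "fp")
                if inventory:
                    bump(cat, "tp" if gid else "fp")
        for ge in gold_doc.events:
            if ge.id in matched_gold:
                continue
            bump("Overall", "fn")
            if inventory:
                bump(inventory.category(ge.event_type), "fn")

    out = {}
    for cat, c in counts.items():
        out[cat] = PRF(c["tp"], c["fp"], c["fn"])
    out.setdefault("Overall", PRF(0, 0, 0))
    return out
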