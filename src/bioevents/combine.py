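"""Set-theoretic model combination and event-origin analysis.

Union and intersection of two systems' outputs work per document, with
event equality given by a :class:`~bioevents.matching.MatchPolicy` rather
than strict identity.  Origin classification places every event of a
combined (stacking) output into exactly one of four classes by whether it
matches the standalone output of the stacked model, the stacker, both, or
neither (NOVEL).  The four classes partition the output: NOVEL is defined
as matching neither standalone output.  Removing NOVEL events (which tend
to be produced by neither base model and are disproportionately wrong)
trades a little recall for precision.
"""

from __future__ import annotations

from dataclasses import replace
from enum import Enum

from .matching import MatchPolicy, events_match, match_events_in_document
from .standoff import EventDocument, EventRecord, StandoffError, Trigger


class OriginClass(Enum):
    ONLY_STACKED = "only_stacked"   # only the stacked (parser) model proposed it
    ONLY_STACKER = "only_stacker"   # only the stacker (joint) model proposed it
    BOTH = "both"
    NOVEL = "novel"


def _matches_some(
    e: EventRecord, doc: EventDocument, other: EventDocument | None, policy: MatchPolicy
) -> bool:
    if other is None:
        return False
    return any(events_match(e, o, policy, doc, other) for o in other.events)


def _closure_ids(doc: EventDocument, roots: set[str]) -> set[str]:
    """Event ids reachable from ``roots`` through event-valued arguments."""
    events = doc.event_by_id()
    out: set[str] = set()
    stack = list(roots)
    while stack:
        eid = stack.pop()
        if eid in out:
            continue
        out.add(eid)
        for _, target in events[eid].args:
            if target in events:
                stack.append(target)
    return out


def _restrict(doc: EventDocument, keep: set[str]) -> EventDocument:
    """Drop all events not in ``keep``, cascading over dangling references."""
    events = doc.event_by_id()
    kept = set(keep)
    changed = True
    while changed:
        changed = False
        for eid in sorted(kept):
            e = events[eid]
            for _, target in e.args:
                if target in events and target not in kept:
                    kept.discard(eid)
                    changed = True
                    break
    new = replace(doc)
    new.events = [e for e in doc.events if e.id in kept]
    new.triggers = list(doc.triggers)
    new.proteins = list(doc.proteins)
    new.extra_lines = []
    new.validate()
    return new


def combine_union(
    a: dict[str, EventDocument], b: dict[str, EventDocument], policy: MatchPolicy
) -> dict[str, EventDocument]:
    """Per document: all events of ``a`` plus every event of ``b`` with no
    match in ``a`` (matched duplicates keep ``a``'s serialization); nested
    arguments of imported events are imported transitively."""
    _check_ids(a, b)
    out: dict[str, EventDocument] = {}
    for doc_id in sorted(set(a) | set(b)):
        da = a.get(doc_id)
        db = b.get(doc_id)
        if da is None:
            out[doc_id] = _restrict(db, {e.id for e in db.events})
            continue
        merged = replace(da)
        merged.events = list(da.events)
        merged.triggers = list(da.triggers)
        merged.proteins = list(da.proteins)
        merged.extra_lines = []
        if db is not None:
            unmatched = {
                e.id for e in db.events if not _matches_some(e, db, da, policy)
            }
            to_import = _closure_ids(db, unmatched)
            _import_events(merged, db, to_import)
        merged.validate()
        out[doc_id] = merged
    return out


def _import_events(dst: EventDocument, src: EventDocument, ids: set[str]) -> None:
    """Copy the given events (a reference-closed set) from src into dst with
    fresh ids; triggers come along, proteins are shared task input."""
    if not ids:
        return
    emap: dict[str, str] = {}
    tmap: dict[str, str] = {}
    enum = sum(1 for _ in dst.events) + 1000
    tnum = 2000
    src_events = src.event_by_id()
    src_triggers = src.trigger_by_id()
    dst_trigger_keys = {(t.event_type, t.span): t.id for t in dst.triggers}
    # topological over src so arguments are mapped before their users
    from .standoff import topological_events

    for e in topological_events(src):
        if e.id not in ids:
            continue
        trg = src_triggers[e.trigger_id]
        key = (trg.event_type, trg.span)
        if key in dst_trigger_keys:
            tid = dst_trigger_keys[key]
        elif trg.id in tmap:
            tid = tmap[trg.id]
        else:
            tnum += 1
            tid = f"TU{tnum}"
            tmap[trg.id] = tid
            dst.triggers.append(Trigger(tid, trg.event_type, trg.span, trg.text))
            dst_trigger_keys[key] = tid
        enum += 1
        eid = f"EU{enum}"
        emap[e.id] = eid
        args = []
        for role, target in e.args:
            if target in src_events:
                if target not in emap:
                    raise StandoffError(
                        f"{src.doc_id}: imported event {e.id} references {target} "
                        "which was neither matched nor importable"
                    )
                args.append((role, emap[target]))
            else:
                args.append((role, target))
        dst.events.append(EventRecord(eid, e.event_type, tid, tuple(args)))


def combine_intersection(
    a: dict[str, EventDocument], b: dict[str, EventDocument], policy: MatchPolicy
) -> dict[str, EventDocument]:
    """Per document: events of ``a`` matching some event of ``b`` one-to-one,
    closed under argument reference (a kept event whose nested argument is
    dropped is itself dropped)."""
    _check_ids(a, b)
    out: dict[str, EventDocument] = {}
    for doc_id in sorted(a):
        da = a[doc_id]
        db = b.get(doc_id)
        if db is None:
            keep: set[str] = set()
        else:
            pairs = match_events_in_document(da, db, policy)
            keep = {pid for pid, gid in pairs if gid}
        out[doc_id] = _restrict(da, keep)
    return out


def classify_origins(
    final: dict[str, EventDocument],
    stacker_alone: dict[str, EventDocument],
    stacked_alone: dict[str, EventDocument],
    policy: MatchPolicy,
) -> dict[tuple[str, str], OriginClass]:
    """Place each event of the combined output in exactly one origin class.

    Keys are ``(doc_id, event_id)``.  BOTH if the event matches both
    standalone outputs, ONLY_* if exactly one, NOVEL if neither — so the
    classes partition the final output.
    """
    out: dict[tuple[str, str], OriginClass] = {}
    for doc_id in sorted(final):
        df = final[doc_id]
        dr = stacker_alone.get(doc_id)
        ds = stacked_alone.get(doc_id)
        for e in df.events:
            in_stacker = _matches_some(e, df, dr, policy)
            in_stacked = _matches_some(e, df, ds, policy)
            if in_stacker and in_stacked:
                cls = OriginClass.BOTH
            elif in_stacker:
                cls = OriginClass.ONLY_STACKER
            elif in_stacked:
                cls = OriginClass.ONLY_STACKED
            else:
                cls = OriginClass.NOVEL
            out[(doc_id, e.id)] = cls
    return out


def remove_novel(
    final: dict[str, EventDocument],
    stacker_alone: dict[str, EventDocument],
    stacked_alone: dict[str, EventDocument],
    policy: MatchPolicy,
) -> dict[str, EventDocument]:
    """Drop NOVEL events from the combined output, cascading over events
    that referenced them."""
    origins = classify_origins(final, stacker_alone, stacked_alone, policy)
    out: dict[str, EventDocument] = {}
    for doc_id in sorted(final):
        doc = final[doc_id]
        keep = {
            e.id
            for e in doc.events
            if origins[(doc_id, e.id)] is not OriginClass.NOVEL
        }
        out[doc_id] = _restrict(doc, keep)
    return out


def origin_counts(
    origins: dict[tuple[str, str], OriginClass]
) -> dict[OriginClass, int]:
    counts = {cls: 0 for cls in OriginClass}
    for cls in origins.values():
        counts[cls] += 1
    return counts


def _check_ids(a: dict[str, EventDocument], b: dict[str, EventDocument]) -> None:
    # union/intersection operate on shared doc id universes; extra ids on
    # either side are tolerated (treated as empty documents on the other)
    return None
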