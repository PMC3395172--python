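"""Reading and writing BioNLP shared-task standoff documents.

A document is a triple of files sharing a basename: ``.txt`` (raw text),
``.a1`` (given entity mentions, typically proteins) and ``.a2`` (event
triggers and events).  Offsets are 0-based, half-open character offsets
into the text.  Event lines reference triggers and other events by id::

    T1\tProtein 28 33\tTRAF2
    T3\tPhosphorylation 8 23\tphosphorylation
    E1\tPhosphorylation:T3 Theme:T1

THEME roles may be numbered (``Theme2``, ``Theme3`` ...) on multi-theme
Binding events; on parse they are normalized to the role ``THEME``
preserving order, and renumbered again on write.  Modifier lines (``M``,
``*`` ...) are preserved verbatim but never interpreted.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace

THEME = "THEME"
CAUSE = "CAUSE"

_ROLE_RE = re.compile(r"^(Theme|Cause)(\d*)$", re.IGNORECASE)


class StandoffError(ValueError):
    """Raised for malformed standoff content or invariant violations."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval [start, end) into the document text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise StandoffError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class ProteinMention:
    id: str
    type: str
    span: Span
    text: str


@dataclass(frozen=True)
class Trigger:
    id: str
    event_type: str
    span: Span
    text: str


@dataclass(frozen=True)
class EventRecord:
    """One event: a typed trigger plus role-labeled arguments.

    ``args`` is an ordered tuple of ``(role, target_id)`` with role in
    {THEME, CAUSE}; targets are protein-mention ids or event ids.
    """

    id: str
    event_type: str
    trigger_id: str
    args: tuple[tuple[str, str], ...]

    def themes(self) -> list[str]:
        return [t for r, t in self.args if r == THEME]

    def causes(self) -> list[str]:
        return [t for r, t in self.args if r == CAUSE]


@dataclass
class EventDocument:
    doc_id: str
    text: str
    proteins: list[ProteinMention] = field(default_factory=list)
    triggers: list[Trigger] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)
    extra_lines: list[str] = field(default_factory=list)

    def protein_by_id(self) -> dict[str, ProteinMention]:
        return {p.id: p for p in self.proteins}

    def trigger_by_id(self) -> dict[str, Trigger]:
        return {t.id: t for t in self.triggers}

    def event_by_id(self) -> dict[str, EventRecord]:
        return {e.id: e for e in self.events}

    def validate(self) -> None:
        validate_document(self)


def _parse_t_line(line: str, lineno: int) -> tuple[str, str, Span, str]:
    parts = line.split("\t")
    if len(parts) < 3:
        raise StandoffError(f"line {lineno}: malformed T-record: {line!r}")
    tid = parts[0]
    try:
        type_, start, end = parts[1].split(" ")
        span = Span(int(start), int(end))
    except (ValueError, StandoffError) as exc:
        raise StandoffError(f"line {lineno}: bad T-record body: {line!r}") from exc
    return tid, type_, span, parts[2]


def _parse_e_line(line: str, lineno: int) -> EventRecord:
    parts = line.split("\t")
    if len(parts) < 2:
        raise StandoffError(f"line {lineno}: malformed E-record: {line!r}")
    eid = parts[0]
    fields = parts[1].split(" ")
    try:
        etype, tid = fields[0].split(":")
    except ValueError as exc:
        raise StandoffError(f"line {lineno}: bad event head: {line!r}") from exc
    args: list[tuple[str, str]] = []
    for f in fields[1:]:
        if not f:
            continue
        try:
            role, target = f.split(":")
        except ValueError as exc:
            raise StandoffError(f"line {lineno}: bad argument {f!r}") from exc
        m = _ROLE_RE.match(role)
        if m is None:
            raise StandoffError(f"line {lineno}: unsupported role {role!r}")
        args.append((m.group(1).upper(), target))
    return EventRecord(eid, etype, tid, tuple(args))


def read_document(
    txt_content: str, a1_content: str, a2_content: str, doc_id: str = "doc"
) -> EventDocument:
    """Parse one standoff triple into a validated :class:`EventDocument`.

    Numbered THEME roles are normalized to THEME (order preserved);
    duplicate triggers with identical span and type are merged to a
    canonical trigger.  Raises :class:`StandoffError` on malformed lines,
    dangling references or cyclic event references.
    """
    doc = EventDocument(doc_id=doc_id, text=txt_content)
    for lineno, line in enumerate(a1_content.splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            raise StandoffError(f"a1 line {lineno}: expected T-record: {line!r}")
        tid, type_, span, text = _parse_t_line(line, lineno)
        doc.proteins.append(ProteinMention(tid, type_, span, text))

    trigger_canon: dict[tuple[str, Span], str] = {}
    trigger_alias: dict[str, str] = {}
    events: list[EventRecord] = []
    for lineno, line in enumerate(a2_content.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            tid, type_, span, text = _parse_t_line(line, lineno)
            key = (type_, span)
            if key in trigger_canon:  # merge textually identical triggers
                trigger_alias[tid] = trigger_canon[key]
            else:
                trigger_canon[key] = tid
                trigger_alias[tid] = tid
                doc.triggers.append(Trigger(tid, type_, span, text))
        elif line.startswith("E"):
            events.append(_parse_e_line(line, lineno))
        else:
            doc.extra_lines.append(line)

    doc.events = [replace(e, trigger_id=trigger_alias.get(e.trigger_id, e.trigger_id))
                  for e in events]
    validate_document(doc)
    return doc


def validate_document(doc: EventDocument) -> None:
    """Check all standoff invariants; raise :class:`StandoffError` otherwise."""
    ids: set[str] = set()
    for obj in (*doc.proteins, *doc.triggers, *doc.events):
        if obj.id in ids:
            raise StandoffError(f"{doc.doc_id}: duplicate id {obj.id}")
        ids.add(obj.id)
    n = len(doc.text)
    for m in (*doc.proteins, *doc.triggers):
        if m.span.end > n:
            raise StandoffError(f"{doc.doc_id}: span of {m.id} exceeds text length")
        if doc.text[m.span.start : m.span.end] != m.text:
            raise StandoffError(
                f"{doc.doc_id}: surface text of {m.id} does not match document text"
            )
    triggers = doc.trigger_by_id()
    proteins = doc.protein_by_id()
    events = doc.event_by_id()
    for e in doc.events:
        trg = triggers.get(e.trigger_id)
        if trg is None:
            raise StandoffError(f"{doc.doc_id}: event {e.id} has dangling trigger {e.trigger_id}")
        if trg.event_type != e.event_type:
            raise StandoffError(
                f"{doc.doc_id}: event {e.id} type {e.event_type} != trigger type {trg.event_type}"
            )
        for role, target in e.args:
            if role not in (THEME, CAUSE):
                raise StandoffError(f"{doc.doc_id}: event {e.id} has bad role {role}")
            if target not in proteins and target not in events:
                raise StandoffError(f"{doc.doc_id}: event {e.id} has dangling target {target}")
    # acyclicity of event->event references
    color: dict[str, int] = {}

    def visit(eid: str) -> None:
        if color.get(eid) == 1:
            raise StandoffError(f"{doc.doc_id}: cyclic event reference through {eid}")
        if color.get(eid) == 2:
            return
        color[eid] = 1
        for _, target in events[eid].args:
            if target in events:
                visit(target)
        color[eid] = 2

    for eid in events:
        visit(eid)


def topological_events(doc: EventDocument) -> list[EventRecord]:
    """Events ordered so every event-valued argument precedes its user."""
    events = doc.event_by_id()
    out: list[EventRecord] = []
    seen: set[str] = set()

    def visit(e: EventRecord) -> None:
        if e.id in seen:
            return
        seen.add(e.id)
        for _, target in e.args:
            if target in events:
                visit(events[target])
        out.append(e)

    for e in doc.events:
        visit(e)
    return out


def write_document(doc: EventDocument) -> tuple[str, str]:
    """Serialize to ``(a1_content, a2_content)``.

    Protein ids are kept (they are task input); trigger ids are renumbered
    after the last protein id, and event ids are renumbered E1..En in
    topological order (arguments before the events that use them).
    Multi-THEME events serialize their themes as Theme, Theme2, Theme3 ...
    """
    validate_document(doc)
    a1_lines = [
        f"{p.id}\t{p.type} {p.span.start} {p.span.end}\t{p.text}" for p in doc.proteins
    ]
    tnum = 0
    for p in doc.proteins:
        m = re.match(r"^T(\d+)$", p.id)
        if m:
            tnum = max(tnum, int(m.group(1)))
    tmap: dict[str, str] = {}
    a2_lines: list[str] = []
    # only triggers actually referenced by events are emitted
    used = {e.trigger_id for e in doc.events}
    for t in doc.triggers:
        if t.id not in used:
            continue
        tnum += 1
        tmap[t.id] = f"T{tnum}"
        a2_lines.append(
            f"T{tnum}\t{t.event_type} {t.span.start} {t.span.end}\t{t.text}"
        )
    emap: dict[str, str] = {}
    ordered = topological_events(doc)
    for i, e in enumerate(ordered, 1):
        emap[e.id] = f"E{i}"
    for e in ordered:
        parts = [f"{emap[e.id]}\t{e.event_type}:{tmap[e.trigger_id]}"]
        theme_no = 0
        for role, target in e.args:
            tgt = emap.get(target, target)
            if role == THEME:
                theme_no += 1
                label = "Theme" if theme_no == 1 else f"Theme{theme_no}"
            else:
                label = "Cause"
            parts.append(f"{label}:{tgt}")
        a2_lines.append(parts[0] + (" " + " ".join(parts[1:]) if parts[1:] else ""))
    a2_lines.extend(doc.extra_lines)
    a1 = "\n".join(a1_lines) + ("\n" if a1_lines else "")
    a2 = "\n".join(a2_lines) + ("\n" if a2_lines else "")
    return a1, a2


# ---------------------------------------------------------------------------
# corpus directory layout: one .txt/.a1/.a2 triple per doc_id


def read_corpus(directory: str) -> dict[str, EventDocument]:
    corpus: dict[str, EventDocument] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".txt"):
            continue
        base = name[: -len(".txt")]
        with open(os.path.join(directory, name), encoding="utf-8") as fh:
            txt = fh.read()
        a1 = a2 = ""
        p1 = os.path.join(directory, base + ".a1")
        p2 = os.path.join(directory, base + ".a2")
        if os.path.exists(p1):
            with open(p1, encoding="utf-8") as fh:
                a1 = fh.read()
        if os.path.exists(p2):
            with open(p2, encoding="utf-8") as fh:
                a2 = fh.read()
        corpus[base] = read_document(txt, a1, a2, doc_id=base)
    return corpus


def write_corpus(corpus: dict[str, EventDocument], directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    for doc_id, doc in corpus.items():
        a1, a2 = write_document(doc)
        for ext, content in ((".txt", doc.text), (".a1", a1), (".a2", a2)):
            with open(os.path.join(directory, doc_id + ext), "w", encoding="utf-8") as fh:
                fh.write(content)
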