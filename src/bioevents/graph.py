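"""Token-graph representation of event structures and the joint constraints.

Events over a sentence are equivalent to a labeled directed graph whose
vertices are the anchor (trigger) and protein tokens: an anchor carries an
event-type label, a labeled edge ``(i, j, role)`` says the token at ``j``
fills ``role`` for an event anchored at ``i``, and an unordered protein
pair in ``binding_pairs`` says those two proteins occur as THEMEs of the
same Binding event.  This is the representation the joint model scores and
the projectivity analysis measures.

The structural constraint set (membership in the feasible set of the joint
model) is:

1. every labeled anchor has at least one outgoing THEME edge;
2. CAUSE edges originate only from cause-licensed anchor labels;
3. every edge target that is a candidate-anchor token is itself labeled;
4. every binding pair {p, q} is witnessed by some Binding-labeled anchor
   with THEME edges to both p and q.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx

from .standoff import (
    CAUSE,
    THEME,
    EventDocument,
    EventRecord,
    ProteinMention,
    Span,
    StandoffError,
    Trigger,
    topological_events,
)

PROTEIN = "PROTEIN"
CANDIDATE_ANCHOR = "CANDIDATE_ANCHOR"
OTHER = "OTHER"


@dataclass(frozen=True)
class Token:
    index: int
    text: str
    span: Span
    kind: str = OTHER
    sentence: int = 0
    ref_id: str | None = None  # protein-mention id for PROTEIN tokens


@dataclass(frozen=True)
class TypeInventory:
    """Event-type inventory with role valences.

    ``simple_types`` take exactly one THEME; ``binding_types`` allow many
    THEMEs; ``regulation_types`` take one THEME (protein or event) and at
    most one CAUSE; ``cause_licensed_types`` are those allowed CAUSE
    arguments (regulations, plus Catalysis on the epigenetics task).
    """

    simple_types: frozenset[str]
    binding_types: frozenset[str]
    regulation_types: frozenset[str]
    cause_licensed_types: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.simple_types, self.binding_types, self.regulation_types]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("type classes must be disjoint")
        extra = self.cause_licensed_types - self.regulation_types - {"Catalysis"}
        if extra:
            raise ValueError(f"cause licensing outside regulations: {extra}")

    @property
    def all_types(self) -> tuple[str, ...]:
        return tuple(
            sorted(self.simple_types | self.binding_types | self.regulation_types)
        )

    def category(self, event_type: str) -> str:
        if event_type in self.simple_types:
            return "Simple"
        if event_type in self.binding_types:
            return "Binding"
        if event_type in self.regulation_types:
            return "Regulation"
        return "Other"

    def event_valued_theme_ok(self, event_type: str) -> bool:
        return event_type in self.regulation_types


def ge_inventory() -> TypeInventory:
    """The Genia-track inventory (5 simple types, Binding, 3 regulations)."""
    regs = frozenset({"Regulation", "Positive_regulation", "Negative_regulation"})
    return TypeInventory(
        simple_types=frozenset(
            {"Gene_expression", "Transcription", "Localization", "Catabolism",
             "Phosphorylation"}
        ),
        binding_types=frozenset({"Binding"}),
        regulation_types=regs,
        cause_licensed_types=regs,
    )


def epi_inventory() -> TypeInventory:
    """Epigenetics-track style inventory; Catalysis is CAUSE-licensed there."""
    return TypeInventory(
        simple_types=frozenset(
            {"Methylation", "Acetylation", "Ubiquitination", "Glycosylation"}
        ),
        binding_types=frozenset(),
        regulation_types=frozenset({"Regulation", "Catalysis"}),
        cause_licensed_types=frozenset({"Regulation", "Catalysis"}),
    )


def id_inventory() -> TypeInventory:
    regs = frozenset({"Regulation", "Positive_regulation", "Negative_regulation"})
    return TypeInventory(
        simple_types=frozenset({"Gene_expression", "Transcription", "Phosphorylation",
                                "Process"}),
        binding_types=frozenset({"Binding"}),
        regulation_types=regs,
        cause_licensed_types=regs,
    )


INVENTORIES = {"ge": ge_inventory, "epi": epi_inventory, "id": id_inventory}


@dataclass
class TokenGraph:
    tokens: list[Token]
    labels: dict[int, str] = field(default_factory=dict)
    edges: set[tuple[int, int, str]] = field(default_factory=set)
    binding_pairs: set[frozenset[int]] = field(default_factory=set)

    def token(self, index: int) -> Token:
        return self.tokens[index]

    def outgoing(self, i: int) -> list[tuple[int, int, str]]:
        return sorted(e for e in self.edges if e[0] == i)


@dataclass(frozen=True)
class Violation:
    code: str
    detail: str


class GraphError(ValueError):
    pass


def _head_token(span: Span, tokens: list[Token], head_index: dict[Span, int]) -> int:
    """Token grounding a (possibly multiword) span: annotated head, else the
    last token covered by the span."""
    if span in head_index:
        return head_index[span]
    covered = [t.index for t in tokens if t.span.start >= span.start and t.span.end <= span.end]
    if not covered:
        raise GraphError(f"span {span} resolves to no token")
    return covered[-1]


def events_to_graph(doc: EventDocument, tokens: list[Token]) -> TokenGraph:
    """Project a document's events onto the labeled token graph.

    Each trigger becomes a labeled anchor token, each argument an edge, and
    each unordered pair of proteins co-occurring as THEMEs of one Binding
    event a binding pair.
    """
    head_index: dict[Span, int] = {}
    for t in tokens:
        head_index.setdefault(t.span, t.index)
    g = TokenGraph(tokens=list(tokens))
    anchor_of: dict[str, int] = {}
    for trg in doc.triggers:
        anchor_of[trg.id] = _head_token(trg.span, tokens, head_index)
    prot_tok: dict[str, int] = {}
    for p in doc.proteins:
        prot_tok[p.id] = _head_token(p.span, tokens, head_index)

    events = doc.event_by_id()
    for e in doc.events:
        i = anchor_of[e.trigger_id]
        g.labels[i] = e.event_type
    for e in doc.events:
        i = anchor_of[e.trigger_id]
        theme_prots: list[int] = []
        for role, target in e.args:
            if target in prot_tok:
                j = prot_tok[target]
                if role == THEME:
                    theme_prots.append(j)
            else:
                j = anchor_of[events[target].trigger_id]
            g.edges.add((i, j, role))
        # unordered pairs of proteins sharing one Binding event
        if len(theme_prots) > 1 and e.event_type.endswith("Binding"):
            for a in range(len(theme_prots)):
                for b in range(a + 1, len(theme_prots)):
                    if theme_prots[a] != theme_prots[b]:
                        g.binding_pairs.add(frozenset({theme_prots[a], theme_prots[b]}))
    return g


def check_constraints(g: TokenGraph, inv: TypeInventory) -> list[Violation]:
    """Return the list of joint-constraint violations (empty iff feasible)."""
    out: list[Violation] = []
    for i, t in sorted(g.labels.items()):
        if g.tokens[i].kind != CANDIDATE_ANCHOR:
            out.append(Violation("label-on-non-anchor", f"token {i}"))
        if not any(s == i and r == THEME for s, _, r in g.edges):
            out.append(Violation("anchor-without-theme", f"token {i} ({t})"))
    for (i, j, r) in sorted(g.edges):
        if i not in g.labels:
            out.append(Violation("edge-from-unlabeled", f"({i},{j},{r})"))
        elif r == CAUSE and g.labels[i] not in inv.cause_licensed_types:
            out.append(Violation("cause-not-licensed", f"({i},{j},{r})"))
        if g.tokens[j].kind == CANDIDATE_ANCHOR and j not in g.labels:
            out.append(Violation("target-unlabeled", f"({i},{j},{r})"))
        elif g.tokens[j].kind == OTHER:
            out.append(Violation("target-not-node", f"({i},{j},{r})"))
    for pair in sorted(g.binding_pairs, key=sorted):
        p, q = sorted(pair)
        if g.tokens[p].kind != PROTEIN or g.tokens[q].kind != PROTEIN:
            out.append(Violation("pair-on-non-protein", f"({p},{q})"))
            continue
        witnessed = any(
            g.labels.get(i) in inv.binding_types
            and (i, p, THEME) in g.edges
            and (i, q, THEME) in g.edges
            for i in g.labels
        )
        if not witnessed:
            out.append(Violation("pair-unwitnessed", f"({p},{q})"))
    return out


def graph_to_events(
    g: TokenGraph,
    inv: TypeInventory,
    doc_id: str = "doc",
    text: str | None = None,
    proteins: list[ProteinMention] | None = None,
) -> EventDocument:
    """Reconstruct an :class:`EventDocument` from a constraint-satisfying graph.

    Binding anchors with several THEME targets are split into events along
    the maximal cliques of the binding-pair relation among those targets
    (singleton events for unpaired targets).  Valences are enforced here:
    simple and regulation anchors keep their first THEME (token order) and
    regulations at most one CAUSE.
    """
    violations = check_constraints(g, inv)
    if violations:
        raise GraphError("constraint-violating graph: " + "; ".join(
            f"{v.code}[{v.detail}]" for v in violations))
    if text is None:
        # reconstruct a text consistent with the token spans
        length = max((t.span.end for t in g.tokens), default=0)
        chars = [" "] * length
        for t in g.tokens:
            chars[t.span.start : t.span.end] = list(t.text)
        text = "".join(chars)
    doc = EventDocument(doc_id=doc_id, text=text)
    if proteins is not None:
        doc.proteins = list(proteins)
        prot_id = {}
        by_span = {p.span: p.id for p in doc.proteins}
        for t in g.tokens:
            if t.kind == PROTEIN:
                prot_id[t.index] = t.ref_id or by_span.get(t.span)
    else:
        prot_id = {}
        n = 0
        for t in g.tokens:
            if t.kind == PROTEIN:
                n += 1
                pid = t.ref_id or f"T{n}"
                prot_id[t.index] = pid
                doc.proteins.append(ProteinMention(pid, "Protein", t.span, t.text))

    tnum = 1000  # trigger ids; renumbered on write anyway
    trig_id: dict[int, str] = {}
    for i in sorted(g.labels):
        tnum += 1
        tid = f"T{tnum}"
        trig_id[i] = tid
        tok = g.tokens[i]
        doc.triggers.append(Trigger(tid, g.labels[i], tok.span, tok.text))

    # the joint constraints allow anchor-argument cycles, but events cannot
    # reference each other cyclically: break cycles by keeping only the
    # forward (smaller-to-larger token index) edges within each strongly
    # connected component of the anchor dependency graph
    dep = nx.DiGraph()
    dep.add_nodes_from(g.labels)
    for (i, j, _r) in g.edges:
        if j in g.labels and i != j:
            dep.add_edge(i, j)
    cyclic_nodes = [scc for scc in nx.strongly_connected_components(dep) if len(scc) > 1]
    edges = set(g.edges)
    for scc in cyclic_nodes:
        edges = {
            (i, j, r)
            for (i, j, r) in edges
            if not (i in scc and j in scc and i > j)
        }
    if edges != g.edges:
        g = TokenGraph(tokens=g.tokens, labels=dict(g.labels), edges=edges,
                       binding_pairs=set(g.binding_pairs))

    # anchors processed bottom-up over the edge DAG (targets before sources)
    order = _anchor_bottom_up_order(g)

    enum = 0
    events_at: dict[int, list[str]] = {i: [] for i in g.labels}
    records: list[EventRecord] = []

    def new_event(etype: str, i: int, args: list[tuple[str, str]]) -> str:
        nonlocal enum
        enum += 1
        eid = f"E{enum}"
        records.append(EventRecord(eid, etype, trig_id[i], tuple(args)))
        events_at[i].append(eid)
        return eid

    for i in order:
        etype = g.labels[i]
        themes = sorted(j for (s, j, r) in g.edges if s == i and r == THEME)
        causes = sorted(j for (s, j, r) in g.edges if s == i and r == CAUSE)

        def target_refs(j: int) -> list[str]:
            if j in prot_id:
                return [prot_id[j]]
            return events_at.get(j, [])

        if etype in inv.binding_types:
            prot_themes = [j for j in themes if j in prot_id]
            other_themes = [j for j in themes if j not in prot_id]
            groups = _binding_groups(prot_themes, g.binding_pairs)
            for grp in groups:
                new_event(etype, i, [(THEME, prot_id[j]) for j in grp])
            for j in other_themes:  # degenerate: event-valued Binding theme
                for ref in target_refs(j):
                    new_event(etype, i, [(THEME, ref)])
        else:
            theme_refs: list[str] = []
            for j in themes:
                theme_refs.extend(target_refs(j))
            if not theme_refs:
                continue  # nested target produced no event; drop anchor
            args: list[tuple[str, str]] = [(THEME, theme_refs[0])]
            if etype in inv.cause_licensed_types and causes:
                for j in causes:
                    refs = target_refs(j)
                    if refs:
                        args.append((CAUSE, refs[0]))
                        break
            new_event(etype, i, args)

    doc.events = records
    doc.validate()
    return doc


def _anchor_bottom_up_order(g: TokenGraph) -> list[int]:
    """Anchors ordered so edge targets precede edge sources."""
    dg = nx.DiGraph()
    dg.add_nodes_from(g.labels)
    for (i, j, _) in g.edges:
        if j in g.labels and i != j:
            dg.add_edge(i, j)
    return list(nx.lexicographical_topological_sort(dg.reverse()))


def _binding_groups(
    prot_themes: list[int], pairs: set[frozenset[int]]
) -> list[list[int]]:
    """Split a Binding anchor's protein THEMEs into events: maximal cliques
    of the pair relation, singletons for unpaired targets."""
    if not prot_themes:
        return []
    sub = nx.Graph()
    sub.add_nodes_from(prot_themes)
    for pair in pairs:
        p, q = sorted(pair)
        if p in sub and q in sub:
            sub.add_edge(p, q)
    groups = [sorted(c) for c in nx.find_cliques(sub)]
    groups.sort()
    return groups


# ---------------------------------------------------------------------------
# token TSV sidecar: index, start, end, text, kind, sentence


def tokens_to_tsv(tokens: list[Token]) -> str:
    buf = io.StringIO()
    for t in tokens:
        buf.write(f"{t.index}\t{t.span.start}\t{t.span.end}\t{t.text}\t{t.kind}\t{t.sentence}\n")
    return buf.getvalue()


def tokens_from_tsv(content: str) -> list[Token]:
    tokens: list[Token] = []
    for line in content.splitlines():
        if not line.strip():
            continue
        idx, start, end, text, kind, sent = line.split("\t")
        tokens.append(Token(int(idx), text, Span(int(start), int(end)), kind, int(sent)))
    if [t.index for t in tokens] != list(range(len(tokens))):
        raise StandoffError("token indices must be contiguous from 0")
    return tokens
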