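"""The stacked model: event extraction as dependency parsing.

Event structures are projected to single-head dependency trees whose nodes
are event anchors and entity tokens plus a virtual root: words taking part
in no event are dropped, multiword anchors collapse to their head token,
and nodes with multiple parents keep one head (the earliest in token
order, THEME preferred over CAUSE on ties).  An edge-factored parser is
trained over these trees with an averaged structured perceptron and
decoded either projectively (first-order Eisner, "1P") or non-projectively
(maximum spanning arborescence / Chu-Liu-Edmonds, "1N").  Trees are
converted back to events, and cross-validated predictions over training
data provide stacking input that reflects test-time accuracy rather than
training-set accuracy.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import networkx as nx

from .graph import (
    CANDIDATE_ANCHOR,
    PROTEIN,
    Token,
    TypeInventory,
    events_to_graph,
)
from .joint import StackedPrediction, _dist_bin
from .standoff import (
    CAUSE,
    THEME,
    EventDocument,
    EventRecord,
    ProteinMention,
    Span,
    Trigger,
)

ROOT = -1
ROOT_ROLE = "ROOT"
ARG_ROLES = (THEME, CAUSE)


@dataclass(frozen=True)
class TreeNode:
    index: int
    kind: str
    event_type: str | None = None


@dataclass
class DependencyTree:
    """Single-head rooted tree: ``heads[d] = (head_index_or_ROOT, role)``."""

    nodes: dict[int, TreeNode]
    heads: dict[int, tuple[int, str]]

    def validate(self) -> None:
        for d, (h, role) in self.heads.items():
            if d not in self.nodes:
                raise ValueError(f"dependent {d} is not a node")
            if h != ROOT and h not in self.nodes:
                raise ValueError(f"head {h} is not a node")
            if h == ROOT and role != ROOT_ROLE:
                raise ValueError("root attachments must carry the ROOT role")
        if set(self.heads) != set(self.nodes):
            raise ValueError("every node needs exactly one head")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_node(ROOT)
        for d, (h, _) in self.heads.items():
            g.add_edge(h, d)
        if not nx.is_arborescence(g):
            raise ValueError("head map is not a rooted tree")

    def children(self, h: int) -> list[tuple[int, str]]:
        return sorted((d, r) for d, (hh, r) in self.heads.items() if hh == h)

    def score(self, scores: dict[tuple[int, int, str], float]) -> float:
        return sum(scores[(h, d, r)] for d, (h, r) in self.heads.items())

    def crossing_count(self) -> int:
        """Crossing arc pairs with the virtual root placed leftmost."""
        pos = {ROOT: min(self.nodes, default=0) - 1}
        ints = sorted(
            (min(pos.get(h, h), d), max(pos.get(h, h), d)) for d, (h, _) in self.heads.items()
        )
        c = 0
        for x in range(len(ints)):
            for y in range(x + 1, len(ints)):
                (a, b), (p, q) = ints[x], ints[y]
                if len({a, b, p, q}) == 4 and (a < p < b < q or p < a < q < b):
                    c += 1
        return c


def project_to_tree(doc: EventDocument, tokens: list[Token]) -> DependencyTree:
    """Project a document's events to a dependency tree.

    Non-participating words are dropped, each anchor is its trigger's head
    token, and nodes with several parents keep the earliest head (THEME
    preferred over CAUSE when the same head assigns both).  Remaining
    parentless nodes attach to the virtual root.
    """
    g = events_to_graph(doc, tokens)
    nodes: dict[int, TreeNode] = {}
    for i, t in g.labels.items():
        nodes[i] = TreeNode(i, CANDIDATE_ANCHOR, t)
    for (_i, j, _r) in g.edges:
        if j not in nodes:
            nodes[j] = TreeNode(j, tokens[j].kind)
    heads: dict[int, tuple[int, str]] = {}
    role_prio = {THEME: 0, CAUSE: 1}
    for (i, j, r) in sorted(g.edges, key=lambda e: (e[1], e[0], role_prio[e[2]])):
        if j not in heads:
            heads[j] = (i, r)
        else:
            h, hr = heads[j]
            if (i, role_prio[r]) < (h, role_prio[hr]):
                heads[j] = (i, r)
    for n in nodes:
        if n not in heads:
            heads[n] = (ROOT, ROOT_ROLE)
    tree = DependencyTree(nodes, heads)
    tree.validate()
    return tree


def tree_to_events(
    tree: DependencyTree,
    inv: TypeInventory,
    doc_id: str = "doc",
    text: str | None = None,
    tokens: list[Token] | None = None,
    proteins: list[ProteinMention] | None = None,
) -> EventDocument:
    """Convert a dependency tree back to event structures.

    Each anchor node with at least one THEME child becomes an event, with
    valences enforced: simple and regulation types keep their first THEME
    (token order), Binding collects all THEME children into one event, and
    at most one CAUSE survives on cause-licensed types.  Anchors without a
    THEME child yield no event; arguments pointing at them are dropped.
    """
    if tokens is None:
        # synthesize placeholder tokens covering every tree node
        tokens = []
        pos = 0
        for i in sorted(tree.nodes):
            word = f"tok{i}"
            tokens.append(
                Token(i, word, Span(pos, pos + len(word)), tree.nodes[i].kind)
            )
            pos += len(word) + 1
    tok_by_index = {t.index: t for t in tokens}
    if text is None:
        length = max((t.span.end for t in tokens), default=0)
        chars = [" "] * length
        for t in tokens:
            chars[t.span.start : t.span.end] = list(t.text)
        text = "".join(chars)

    doc = EventDocument(doc_id=doc_id, text=text)
    prot_id: dict[int, str] = {}
    if proteins is not None:
        doc.proteins = list(proteins)
        by_span = {p.span: p.id for p in doc.proteins}
        for t in tokens:
            if t.kind == PROTEIN and t.span in by_span:
                prot_id[t.index] = by_span[t.span]
    else:
        n = 0
        for i, node in sorted(tree.nodes.items()):
            if node.kind == PROTEIN and i in tok_by_index:
                n += 1
                pid = f"T{n}"
                prot_id[i] = pid
                tok = tok_by_index[i]
                doc.proteins.append(ProteinMention(pid, "Protein", tok.span, tok.text))

    anchors = [i for i, n in sorted(tree.nodes.items()) if n.kind == CANDIDATE_ANCHOR]
    # bottom-up: children before parents
    depth: dict[int, int] = {}

    def get_depth(i: int) -> int:
        if i in depth:
            return depth[i]
        h, _ = tree.heads[i]
        depth[i] = 0 if h == ROOT else get_depth(h) + 1
        return depth[i]

    anchors.sort(key=lambda i: -get_depth(i))

    tnum = 0
    enum = 0
    event_at: dict[int, str] = {}
    records: list[EventRecord] = []
    trig_of: dict[int, str] = {}

    for i in anchors:
        node = tree.nodes[i]
        etype = node.event_type
        if etype is None:
            continue
        kids = tree.children(i)
        theme_refs: list[str] = []
        cause_refs: list[str] = []
        for d, r in kids:
            if r not in ARG_ROLES:
                continue
            if d in prot_id:
                ref = prot_id[d]
            elif d in event_at:
                ref = event_at[d]
            else:
                continue  # argument anchor formed no event
            (theme_refs if r == THEME else cause_refs).append(ref)
        if not theme_refs:
            continue
        if etype in inv.binding_types:
            args = [(THEME, ref) for ref in theme_refs]
        else:
            args = [(THEME, theme_refs[0])]
            if etype in inv.cause_licensed_types and cause_refs:
                args.append((CAUSE, cause_refs[0]))
        tnum += 1
        tid = f"TT{tnum}"
        trig_of[i] = tid
        tok = tok_by_index[i]
        doc.triggers.append(Trigger(tid, etype, tok.span, tok.text))
        enum += 1
        eid = f"E{enum}"
        event_at[i] = eid
        records.append(EventRecord(eid, etype, tid, tuple(args)))

    doc.events = records
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# decoders


def _best_role_scores(
    node_ids: list[int], edge_scores: dict[tuple[int, int, str], float]
):
    """Collapse role-labeled scores to the best role per (head, dependent)."""
    best: dict[tuple[int, int], tuple[float, str]] = {}
    for d in node_ids:
        best[(ROOT, d)] = (edge_scores[(ROOT, d, ROOT_ROLE)], ROOT_ROLE)
        for h in node_ids:
            if h == d:
                continue
            options = [(edge_scores[(h, d, r)], r) for r in ARG_ROLES]
            options.sort(key=lambda x: (-x[0], x[1] != THEME))
            best[(h, d)] = options[0]
    return best


def decode_projective(
    node_ids: list[int],
    edge_scores: dict[tuple[int, int, str], float],
    node_meta: dict[int, TreeNode] | None = None,
) -> DependencyTree:
    """First-order projective decoding (Eisner's algorithm).

    The virtual root sits leftmost; the returned tree has zero crossing
    arcs by construction.
    """
    order = sorted(node_ids)
    best = _best_role_scores(order, edge_scores)
    seq = [ROOT] + order  # positions 0..n
    n = len(seq)
    if n == 1:
        return DependencyTree({}, {})
    NEG = float("-inf")

    def arc(hp: int, dp: int) -> float:
        return best[(seq[hp], seq[dp])][0]

    # [s][t][dir][complete]: dir 0 = left (head at t), 1 = right (head at s)
    score = [[[[NEG, NEG], [NEG, NEG]] for _ in range(n)] for _ in range(n)]
    back = [[[[None, None], [None, None]] for _ in range(n)] for _ in range(n)]
    for s in range(n):
        for d in (0, 1):
            for c in (0, 1):
                score[s][s][d][c] = 0.0
    for length in range(1, n):
        for s in range(n - length):
            t = s + length
            # incomplete spans
            for r in range(s, t):
                base = score[s][r][1][1] + score[r + 1][t][0][1]
                if base == NEG:
                    continue
                if s != 0:  # the root is never a dependent
                    val = base + arc(t, s)
                    if val > score[s][t][0][0]:
                        score[s][t][0][0] = val
                        back[s][t][0][0] = r
                val = base + arc(s, t)
                if val > score[s][t][1][0]:
                    score[s][t][1][0] = val
                    back[s][t][1][0] = r
            # complete spans
            for r in range(s, t):
                val = score[s][r][0][1] + score[r][t][0][0]
                if val > score[s][t][0][1]:
                    score[s][t][0][1] = val
                    back[s][t][0][1] = r
            for r in range(s + 1, t + 1):
                val = score[s][r][1][0] + score[r][t][1][1]
                if val > score[s][t][1][1]:
                    score[s][t][1][1] = val
                    back[s][t][1][1] = r

    heads_pos: dict[int, int] = {}

    def recover(s: int, t: int, d: int, c: int) -> None:
        if s == t:
            return
        r = back[s][t][d][c]
        if c == 0:
            if d == 0:
                heads_pos[s] = t
            else:
                heads_pos[t] = s
            recover(s, r, 1, 1)
            recover(r + 1, t, 0, 1)
        else:
            if d == 0:
                recover(s, r, 0, 1)
                recover(r, t, 0, 0)
            else:
                recover(s, r, 1, 0)
                recover(r, t, 1, 1)

    recover(0, n - 1, 1, 1)
    heads: dict[int, tuple[int, str]] = {}
    for dp, hp in heads_pos.items():
        d_id, h_id = seq[dp], seq[hp]
        heads[d_id] = (h_id, best[(h_id, d_id)][1])
    nodes = {
        i: (node_meta[i] if node_meta else TreeNode(i, CANDIDATE_ANCHOR)) for i in order
    }
    tree = DependencyTree(nodes, heads)
    tree.validate()
    return tree


def decode_nonprojective(
    node_ids: list[int],
    edge_scores: dict[tuple[int, int, str], float],
    node_meta: dict[int, TreeNode] | None = None,
) -> DependencyTree:
    """Maximum spanning arborescence decoding (Chu-Liu/Edmonds)."""
    order = sorted(node_ids)
    if not order:
        return DependencyTree({}, {})
    best = _best_role_scores(order, edge_scores)
    shift = -min(v for v, _ in best.values()) + 1.0
    g = nx.DiGraph()
    g.add_node(ROOT)
    for d in order:
        g.add_edge(ROOT, d, weight=best[(ROOT, d)][0] + shift)
        for h in order:
            if h != d:
                g.add_edge(h, d, weight=best[(h, d)][0] + shift)
    arb = nx.maximum_spanning_arborescence(g, attr="weight")
    heads: dict[int, tuple[int, str]] = {}
    for h, d in arb.edges:
        heads[d] = (h, best[(h, d)][1])
    nodes = {
        i: (node_meta[i] if node_meta else TreeNode(i, CANDIDATE_ANCHOR)) for i in order
    }
    tree = DependencyTree(nodes, heads)
    tree.validate()
    return tree


DECODERS = {"1p": decode_projective, "1n": decode_nonprojective}


# ---------------------------------------------------------------------------
# features, training, prediction


def edge_features(
    tokens: list[Token], h: int, d: int, role: str
) -> dict[str, float]:
    wd = tokens[d].text
    kd = tokens[d].kind
    if h == ROOT:
        return {
            f"P|root|dw={wd}|r={role}": 1.0,
            f"P|root|dk={kd}|r={role}": 1.0,
        }
    wh = tokens[h].text
    dist = _dist_bin(d - h)
    return {
        f"P|hw={wh}|dw={wd}|r={role}": 1.0,
        f"P|hw={wh}|d={dist}|r={role}": 1.0,
        f"P|hk={tokens[h].kind}|dk={kd}|d={dist}|r={role}": 1.0,
        f"P|bias|r={role}": 1.0,
    }


def anchor_type_features(tokens: list[Token], i: int, t: str) -> dict[str, float]:
    w = tokens[i].text
    return {f"A|w={w}|t={t}": 1.0, f"A|pre={w[:3]}|t={t}": 1.0, f"A|bias|t={t}": 1.0}


@dataclass
class ParserInstance:
    doc_id: str
    tokens: list[Token]
    gold_tree: DependencyTree | None = None

    def __post_init__(self) -> None:
        self.node_ids = sorted(
            t.index for t in self.tokens if t.kind in (PROTEIN, CANDIDATE_ANCHOR)
        )


def training_instance(doc: EventDocument, tokens: list[Token]) -> ParserInstance:
    """Gold tree over all candidate nodes: the event projection, with
    non-participating candidates attached to the virtual root."""
    proj = project_to_tree(doc, tokens)
    nodes = dict(proj.nodes)
    heads = dict(proj.heads)
    for t in tokens:
        if t.kind in (PROTEIN, CANDIDATE_ANCHOR) and t.index not in nodes:
            nodes[t.index] = TreeNode(t.index, t.kind)
            heads[t.index] = (ROOT, ROOT_ROLE)
    tree = DependencyTree(nodes, heads)
    tree.validate()
    return ParserInstance(doc.doc_id, tokens, tree)


class ParserModel:
    """Edge-factored parser weights + anchor-type classifier (both averaged
    perceptrons)."""

    def __init__(self, inventory: TypeInventory, decoder: str = "1p") -> None:
        if decoder not in DECODERS:
            raise ValueError(f"unknown decoder {decoder!r}")
        self.inventory = inventory
        self.decoder = decoder
        self.w: dict[str, float] = {}
        self._acc: dict[str, float] = {}
        self._step = 0
        self._averaged: dict[str, float] | None = None

    def _dot(self, feats: dict[str, float], w: dict[str, float]) -> float:
        return sum(w.get(k, 0.0) * v for k, v in feats.items())

    def _add(self, feats: dict[str, float], scale: float) -> None:
        for k, v in feats.items():
            self.w[k] = self.w.get(k, 0.0) + scale * v
            self._acc[k] = self._acc.get(k, 0.0) + self._step * scale * v
        self._averaged = None

    def averaged(self) -> dict[str, float]:
        if self._averaged is None:
            step = max(self._step, 1)
            self._averaged = {
                k: self.w[k] - self._acc.get(k, 0.0) / step for k in self.w
            }
        return self._averaged

    def edge_score_table(
        self, inst: ParserInstance, use_averaged: bool = True
    ) -> dict[tuple[int, int, str], float]:
        w = self.averaged() if use_averaged else self.w
        scores: dict[tuple[int, int, str], float] = {}
        for d in inst.node_ids:
            scores[(ROOT, d, ROOT_ROLE)] = self._dot(
                edge_features(inst.tokens, ROOT, d, ROOT_ROLE), w
            )
            for h in inst.node_ids:
                if h == d:
                    continue
                for r in ARG_ROLES:
                    scores[(h, d, r)] = self._dot(edge_features(inst.tokens, h, d, r), w)
        return scores

    def decode(self, inst: ParserInstance, use_averaged: bool = True) -> DependencyTree:
        scores = self.edge_score_table(inst, use_averaged)
        meta = {
            i: TreeNode(i, inst.tokens[i].kind) for i in inst.node_ids
        }
        tree = DECODERS[self.decoder](inst.node_ids, scores, meta)
        # assign event types to active anchors via the type classifier
        typed: dict[int, TreeNode] = {}
        for i, node in tree.nodes.items():
            active = node.kind == CANDIDATE_ANCHOR and any(
                r == THEME for _, r in tree.children(i)
            )
            typed[i] = TreeNode(i, node.kind, self.classify_anchor(inst.tokens, i) if active else None)
        return DependencyTree(typed, dict(tree.heads))

    def classify_anchor(self, tokens: list[Token], i: int, use_averaged: bool = True) -> str:
        w = self.averaged() if use_averaged else self.w
        types = self.inventory.all_types
        scored = [
            (self._dot(anchor_type_features(tokens, i, t), w), t) for t in types
        ]
        scored.sort(key=lambda x: (-x[0], x[1]))
        return scored[0][1]


def train_parser(
    instances: list[ParserInstance],
    inventory: TypeInventory,
    epochs: int = 10,
    seed: int = 0,
    decoder: str = "1p",
) -> ParserModel:
    """Averaged structured perceptron against the chosen decoder."""
    if not instances:
        raise ValueError("empty training corpus")
    model = ParserModel(inventory, decoder)
    rng = random.Random(seed)
    order = list(range(len(instances)))
    for _epoch in range(epochs):
        rng.shuffle(order)
        for idx in order:
            inst = instances[idx]
            gold = inst.gold_tree
            model._step += 1
            pred = _decode_raw(model, inst)
            gold_edges = {(h, d, r) for d, (h, r) in gold.heads.items()}
            pred_edges = {(h, d, r) for d, (h, r) in pred.heads.items()}
            for (h, d, r) in gold_edges - pred_edges:
                model._add(edge_features(inst.tokens, h, d, r), +1.0)
            for (h, d, r) in pred_edges - gold_edges:
                model._add(edge_features(inst.tokens, h, d, r), -1.0)
            # anchor-type classifier updates on gold anchors
            for i, node in gold.nodes.items():
                if node.event_type is None:
                    continue
                guess = model.classify_anchor(inst.tokens, i, use_averaged=False)
                if guess != node.event_type:
                    model._add(anchor_type_features(inst.tokens, i, node.event_type), +1.0)
                    model._add(anchor_type_features(inst.tokens, i, guess), -1.0)
    return model


def _decode_raw(model: ParserModel, inst: ParserInstance) -> DependencyTree:
    """Decode with the raw (non-averaged) weights, for perceptron training."""
    scores = model.edge_score_table(inst, use_averaged=False)
    meta = {i: TreeNode(i, inst.tokens[i].kind) for i in inst.node_ids}
    return DECODERS[model.decoder](inst.node_ids, scores, meta)


def parser_prediction(
    model: ParserModel, inst: ParserInstance, tag: str | None = None
) -> StackedPrediction:
    """Decode and expose the result as a stacked prediction (h map + arcs)."""
    tree = model.decode(inst)
    h = {i: n.event_type for i, n in tree.nodes.items() if n.event_type is not None}
    arcs = frozenset(
        (hd, d, r)
        for d, (hd, r) in tree.heads.items()
        if hd != ROOT and r in ARG_ROLES and hd in h
    )
    return StackedPrediction(system_tag=tag or f"parser-{model.decoder}", h=h, arcs=arcs)


def parser_document(
    model: ParserModel,
    inst: ParserInstance,
    doc: EventDocument,
) -> EventDocument:
    """Decode one document and serialize the tree back to events."""
    tree = model.decode(inst)
    return tree_to_events(
        tree,
        model.inventory,
        doc_id=doc.doc_id,
        text=doc.text,
        tokens=inst.tokens,
        proteins=doc.proteins,
    )


@dataclass(frozen=True)
class FoldPlan:
    n_folds: int
    assignment: dict[str, int] = field(hash=False, compare=False, default_factory=dict)
    seed: int = 0

    @staticmethod
    def build(doc_ids: list[str], n_folds: int, seed: int) -> "FoldPlan":
        if n_folds < 2:
            raise ValueError("need at least 2 folds")
        if n_folds > len(doc_ids):
            raise ValueError("more folds than documents")
        ids = sorted(doc_ids)
        rng = random.Random(seed)
        rng.shuffle(ids)
        return FoldPlan(
            n_folds, {doc_id: k % n_folds for k, doc_id in enumerate(ids)}, seed
        )


def stacked_predictions(
    corpus: dict[str, tuple[EventDocument, list[Token]]],
    inventory: TypeInventory,
    n_folds: int,
    seed: int = 0,
    decoder: str = "1p",
    epochs: int = 5,
    tag: str | None = None,
) -> dict[str, StackedPrediction]:
    """Cross-validated stacking input: each document is predicted by a model
    trained on the other folds, so the stacker sees test-time-like accuracy
    rather than training-set accuracy."""
    plan = FoldPlan.build(list(corpus), n_folds, seed)
    instances = {
        doc_id: training_instance(doc, tokens) for doc_id, (doc, tokens) in corpus.items()
    }
    out: dict[str, StackedPrediction] = {}
    for fold in range(n_folds):
        train_ids = [d for d, k in plan.assignment.items() if k != fold]
        test_ids = sorted(d for d, k in plan.assignment.items() if k == fold)
        if not test_ids:
            raise ValueError(f"fold {fold} has zero documents")
        model = train_parser(
            [instances[d] for d in sorted(train_ids)], inventory,
            epochs=epochs, seed=seed + fold, decoder=decoder,
        )
        for doc_id in test_ids:
            out[doc_id] = parser_prediction(model, instances[doc_id], tag=tag)
    return out


def merge_corpora(
    primary: dict[str, EventDocument],
    auxiliary: dict[str, EventDocument],
    replication: int,
) -> dict[str, EventDocument]:
    """Domain-adaptation training multiset: auxiliary once plus the primary
    corpus ``replication`` times, doc ids suffixed per copy."""
    if replication < 1:
        raise ValueError("replication must be >= 1")
    out: dict[str, EventDocument] = {}
    for doc_id, doc in auxiliary.items():
        out[f"{doc_id}#aux"] = replace(doc, doc_id=f"{doc_id}#aux")
    for k in range(1, replication + 1):
        for doc_id, doc in primary.items():
            out[f"{doc_id}#x{k}"] = replace(doc, doc_id=f"{doc_id}#x{k}")
    return out
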