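"""The joint event-extraction model (the "stacker").

Events in a sentence are encoded by three families of binary variables:
``e[i,t]`` (the token at position ``i`` carries event label ``t``),
``a[i,j,r]`` (an event anchored at ``i`` has an argument with role ``r``
grounded at token ``j``) and ``b[p,q]`` (the entity mentions at ``p`` and
``q`` appear as THEMEs of the same Binding event).  The model scores each
part in isolation,

    s(e, a, b) = sum_{e[i,t]=1} s_T(i,t) + sum_{a[i,j,r]=1} s_R(i,j,r)
                 + sum_{b[p,q]=1} s_B(p,q),

with s_T = <w_T, f_T(i,t)> and analogously for s_R, s_B; jointness comes
from the structural constraints (see :mod:`bioevents.graph`).  Inference
maximizes s over the feasible set by dual decomposition with three
subproblems: per-anchor label + outgoing edges, per-token label + incoming
edges, and binding-pair selection.  Learning is 1-best MIRA with weight
averaging.

Stacking augments the local feature functions with indicators of another
system's predictions: for each stacked system S and anchor candidate,
an indicator keyed by (S, proposed label t, S's label at i) — and, at the
argument level, (S, proposed role r, S's role for the arc) — so the
learner can weight every combination of what it wants to predict against
what S predicted.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations

from .graph import (
    CANDIDATE_ANCHOR,
    PROTEIN,
    Token,
    TokenGraph,
    TypeInventory,
    check_constraints,
    events_to_graph,
)
from .standoff import CAUSE, THEME, EventDocument

OPTIMAL = "OPTIMAL"
HEURISTIC = "HEURISTIC"

NONE_LABEL = "NONE"


@dataclass(frozen=True)
class JointAssignment:
    e: frozenset  # of (i, t)
    a: frozenset  # of (i, j, r)
    b: frozenset  # of frozenset({p, q})

    @staticmethod
    def empty() -> "JointAssignment":
        return JointAssignment(frozenset(), frozenset(), frozenset())

    def to_graph(self, tokens: list[Token]) -> TokenGraph:
        return TokenGraph(
            tokens=list(tokens),
            labels=dict(self.e),
            edges=set(self.a),
            binding_pairs=set(self.b),
        )


@dataclass(frozen=True)
class StackedPrediction:
    """One stacked system's output on one document: token-level event labels
    and role-labeled arcs."""

    system_tag: str
    h: dict[int, str] = field(default_factory=dict, hash=False, compare=False)
    arcs: frozenset = frozenset()  # of (i, j, role)

    def __post_init__(self) -> None:
        for (i, _j, _r) in self.arcs:
            if i not in self.h:
                raise ValueError(f"arc source {i} has no anchor label in {self.system_tag}")


def prediction_from_document(
    doc: EventDocument, tokens: list[Token], tag: str
) -> StackedPrediction:
    """View a document's events as a stacked prediction (label map + arcs)."""
    g = events_to_graph(doc, tokens)
    return StackedPrediction(system_tag=tag, h=dict(g.labels), arcs=frozenset(g.edges))


@dataclass
class SentenceInstance:
    doc_id: str
    tokens: list[Token]
    gold: JointAssignment | None = None

    def __post_init__(self) -> None:
        self.anchors = [t.index for t in self.tokens if t.kind == CANDIDATE_ANCHOR]
        self.proteins = [t.index for t in self.tokens if t.kind == PROTEIN]


# ---------------------------------------------------------------------------
# features


def _dist_bin(d: int) -> str:
    sign = "-" if d < 0 else "+"
    m = abs(d)
    if m <= 3:
        return f"{sign}{m}"
    if m <= 6:
        return f"{sign}4-6"
    return f"{sign}7+"


class FeatureExtractor:
    """Local feature functions f_T, f_R, f_B with optional stacking inputs.

    ``stack_mode`` selects which stacked information enters the model:
    ``"both"`` (anchors and arguments), ``"anchors"``, ``"arguments"`` or
    ``None``.  ``conjoin`` additionally duplicates every base feature with
    the stacked label appended to its key (higher capacity, sparser data).
    """

    def __init__(
        self,
        inventory: TypeInventory,
        stacked: list[StackedPrediction] | None = None,
        stack_mode: str | None = "both",
        conjoin: bool = False,
        keep_base_on_conjoin: bool = True,
    ) -> None:
        self.inventory = inventory
        self.stacked = list(stacked or [])
        self.stack_mode = stack_mode if self.stacked else None
        self.conjoin = conjoin
        self.keep_base_on_conjoin = keep_base_on_conjoin

    def with_stacked(self, stacked: list[StackedPrediction] | None) -> "FeatureExtractor":
        fx = FeatureExtractor(
            self.inventory, stacked,
            stack_mode=self.stack_mode or "both",
            conjoin=self.conjoin,
            keep_base_on_conjoin=self.keep_base_on_conjoin,
        )
        return fx

    # -- anchor features ----------------------------------------------------
    def f_T(self, inst: SentenceInstance, i: int, t: str) -> dict[str, float]:
        w = inst.tokens[i].text
        base = {
            f"T|w={w}|t={t}": 1.0,
            f"T|pre={w[:3]}|t={t}": 1.0,
            f"T|bias|t={t}": 1.0,
        }
        feats = dict(base) if (not self.conjoin or self.keep_base_on_conjoin) else {}
        if self.stack_mode in ("both", "anchors"):
            for s in self.stacked:
                h = s.h.get(i, NONE_LABEL)
                feats[f"T|S={s.system_tag}|t={t}|hS={h}"] = 1.0
        if self.conjoin:
            for s in self.stacked:
                h = s.h.get(i, NONE_LABEL)
                for k, v in base.items():
                    feats[f"{k}&hS[{s.system_tag}]={h}"] = v
        return feats

    # -- argument features --------------------------------------------------
    def f_R(self, inst: SentenceInstance, i: int, j: int, r: str) -> dict[str, float]:
        wi = inst.tokens[i].text
        wj = inst.tokens[j].text
        kj = inst.tokens[j].kind
        d = _dist_bin(j - i)
        base = {
            f"R|sw={wi}|tw={wj}|r={r}": 1.0,
            f"R|sw={wi}|d={d}|r={r}": 1.0,
            f"R|tk={kj}|d={d}|r={r}": 1.0,
            f"R|bias|r={r}": 1.0,
        }
        feats = dict(base) if (not self.conjoin or self.keep_base_on_conjoin) else {}
        if self.stack_mode in ("both", "arguments"):
            for s in self.stacked:
                rs = NONE_LABEL
                for (si, sj, sr) in s.arcs:
                    if si == i and sj == j:
                        rs = sr
                        break
                feats[f"R|S={s.system_tag}|r={r}|rS={rs}"] = 1.0
        if self.conjoin:
            for s in self.stacked:
                h = s.h.get(i, NONE_LABEL)
                for k, v in base.items():
                    feats[f"{k}&hS[{s.system_tag}]={h}"] = v
        return feats

    # -- binding pair features ------------------------------------------------
    def f_B(self, inst: SentenceInstance, p: int, q: int) -> dict[str, float]:
        p, q = sorted((p, q))
        wp = inst.tokens[p].text
        wq = inst.tokens[q].text
        return {
            f"B|w1={wp}|w2={wq}": 1.0,
            f"B|d={_dist_bin(q - p)}": 1.0,
            "B|bias": 1.0,
        }


def stacking_features(
    preds: list[StackedPrediction], i: int, t: str
) -> dict[str, float]:
    """The anchor-level stacking indicators alone: for each stacked system S
    an indicator keyed by (S, candidate type t, S's predicted label at i),
    with a NONE bucket when S predicts no anchor at i."""
    feats: dict[str, float] = {}
    for s in preds:
        h = s.h.get(i, NONE_LABEL)
        feats[f"T|S={s.system_tag}|t={t}|hS={h}"] = 1.0
    return feats


def conjoin_features(
    base: dict[str, float], pred: StackedPrediction, i: int, keep_base: bool = True
) -> dict[str, float]:
    """Duplicate every base feature with the stacked system's label at ``i``
    appended to the key; optionally retain the originals."""
    h = pred.h.get(i, NONE_LABEL)
    out = dict(base) if keep_base else {}
    for k, v in base.items():
        out[f"{k}&hS[{pred.system_tag}]={h}"] = v
    return out


# ---------------------------------------------------------------------------
# weights and scoring


class Weights:
    """Sparse weight vector with an accumulator for weight averaging."""

    def __init__(self) -> None:
        self.w: dict[str, float] = {}
        self._acc: dict[str, float] = {}
        self._step = 0

    def dot(self, feats: dict[str, float], averaged: bool = False) -> float:
        if averaged:
            step = max(self._step, 1)
            return sum(
                (self.w.get(k, 0.0) - self._acc.get(k, 0.0) / step) * v
                for k, v in feats.items()
            )
        w = self.w
        return sum(w.get(k, 0.0) * v for k, v in feats.items())

    def add(self, feats: dict[str, float], scale: float) -> None:
        for k, v in feats.items():
            delta = scale * v
            self.w[k] = self.w.get(k, 0.0) + delta
            self._acc[k] = self._acc.get(k, 0.0) + self._step * delta

    def tick(self) -> None:
        self._step += 1

    def averaged_view(self) -> dict[str, float]:
        step = max(self._step, 1)
        return {k: self.w[k] - self._acc.get(k, 0.0) / step for k in self.w}


class ScoredInstance:
    """Per-instance cache of feature vectors and their current scores."""

    def __init__(self, inst: SentenceInstance, fx: FeatureExtractor) -> None:
        self.inst = inst
        self.fx = fx
        inv = fx.inventory
        self.labels = inv.all_types
        self.featT: dict[tuple[int, str], dict[str, float]] = {}
        self.featR: dict[tuple[int, int, str], dict[str, float]] = {}
        self.featB: dict[frozenset, dict[str, float]] = {}
        for i in inst.anchors:
            for t in self.labels:
                self.featT[(i, t)] = fx.f_T(inst, i, t)
            for j in inst.proteins + [k for k in inst.anchors if k != i]:
                for r in (THEME, CAUSE):
                    self.featR[(i, j, r)] = fx.f_R(inst, i, j, r)
        for p, q in combinations(inst.proteins, 2):
            self.featB[frozenset((p, q))] = fx.f_B(inst, p, q)

    def scores(self, w: Weights, averaged: bool = False):
        sT = {k: w.dot(f, averaged) for k, f in self.featT.items()}
        sR = {k: w.dot(f, averaged) for k, f in self.featR.items()}
        sB = {k: w.dot(f, averaged) for k, f in self.featB.items()}
        return sT, sR, sB

    def assignment_features(self, y: JointAssignment) -> dict[str, float]:
        feats: dict[str, float] = {}
        for key in y.e:
            for k, v in self.featT[key].items():
                feats[k] = feats.get(k, 0.0) + v
        for key in y.a:
            for k, v in self.featR[key].items():
                feats[k] = feats.get(k, 0.0) + v
        for key in y.b:
            for k, v in self.featB[key].items():
                feats[k] = feats.get(k, 0.0) + v
        return feats


def score_assignment(y: JointAssignment, sT, sR, sB) -> float:
    """s(e, a, b): sum of local scores over active variables only."""
    return (
        sum(sT[k] for k in y.e)
        + sum(sR[k] for k in y.a)
        + sum(sB[k] for k in y.b)
    )


# ---------------------------------------------------------------------------
# dual decomposition inference


def _solve_outgoing(
    i: int,
    labels: tuple[str, ...],
    inv: TypeInventory,
    anchors: list[int],
    proteins: list[int],
    adjT,
    adjR,
    lam: dict[frozenset, float],
):
    """Best label + outgoing edge set for one candidate anchor.

    Exact: enumerates subsets of protein THEME targets (for binding-pair
    multiplier bonuses) and treats remaining edges independently.  Returns
    (value, label_or_None, edges, witnessed_pairs).
    """
    anchor_targets = [j for j in anchors if j != i]
    best = (0.0, None, frozenset(), frozenset())
    nP = len(proteins)
    for t in labels:
        licensed = t in inv.cause_licensed_types
        binding = t in inv.binding_types
        indep_edges = []
        indep = 0.0
        best_anchor_theme = None
        for j in anchor_targets:
            sth = adjR[(i, j, THEME)]
            if sth > 0:
                indep_edges.append((i, j, THEME))
                indep += sth
            if best_anchor_theme is None or sth > best_anchor_theme[0]:
                best_anchor_theme = (sth, (i, j, THEME))
            if licensed:
                sc = adjR[(i, j, CAUSE)]
                if sc > 0:
                    indep_edges.append((i, j, CAUSE))
                    indep += sc
        if licensed:
            for p in proteins:
                sc = adjR[(i, p, CAUSE)]
                if sc > 0:
                    indep_edges.append((i, p, CAUSE))
                    indep += sc
        has_pos_anchor_theme = any(e[2] == THEME for e in indep_edges)
        base = adjT[(i, t)] + indep
        pair_bonus_live = binding and nP > 1 and any(
            lam.get(frozenset(pq), 0.0) > 0 for pq in combinations(proteins, 2)
        )
        if not pair_bonus_live:
            # no live pair multipliers: protein THEMEs decompose per edge
            psub = [p for p in proteins if adjR[(i, p, THEME)] > 0]
            sc = base + sum(adjR[(i, p, THEME)] for p in psub)
            edges = list(indep_edges) + [(i, p, THEME) for p in psub]
            if not psub and not has_pos_anchor_theme:
                forced = max(
                    [(adjR[(i, p, THEME)], (i, p, THEME)) for p in proteins]
                    + ([best_anchor_theme] if best_anchor_theme else []),
                    default=None,
                )
                if forced is None:
                    continue
                sc += forced[0]
                edges.append(forced[1])
            pairs = (
                [frozenset(pq) for pq in combinations(sorted(psub), 2)]
                if binding else []
            )
            if sc > best[0] + 1e-12:
                best = (sc, t, frozenset(edges), frozenset(pairs))
            continue
        for mask in range(1 << nP):
            psub = [proteins[k] for k in range(nP) if mask >> k & 1]
            sc = base + sum(adjR[(i, p, THEME)] for p in psub)
            pairs: list[frozenset] = []
            if binding and len(psub) > 1:
                for p, q in combinations(psub, 2):
                    key = frozenset((p, q))
                    sc += lam.get(key, 0.0)
                    pairs.append(key)
            edges = list(indep_edges) + [(i, p, THEME) for p in psub]
            if not psub and not has_pos_anchor_theme:
                # at least one THEME is required: force the best candidate
                if best_anchor_theme is None:
                    continue
                sc += best_anchor_theme[0]
                edges.append(best_anchor_theme[1])
            if sc > best[0] + 1e-12:
                best = (sc, t, frozenset(edges), frozenset(pairs))
    return best


def _solve_incoming(
    j: int,
    is_anchor: bool,
    labels: tuple[str, ...],
    sources: list[int],
    adjT,
    adjR,
):
    """Best label + incoming edge set for one token (the mirror subproblem:
    it enforces that argument targets which are anchors carry a label)."""
    pos = []
    total = 0.0
    for i in sources:
        for r in (THEME, CAUSE):
            s = adjR[(i, j, r)]
            if s > 0:
                pos.append((i, j, r))
                total += s
    if not is_anchor:
        return (total, None, frozenset(pos))
    best = (0.0, None, frozenset())
    for t in labels:
        sc = adjT[(j, t)] + total
        if sc > best[0] + 1e-12:
            best = (sc, t, frozenset(pos))
    return best


def _repair(
    e_map: dict[int, str],
    a_set: set,
    inv: TypeInventory,
    proteins: set[int],
    sB,
) -> JointAssignment:
    """Project an outgoing-subproblem solution into the feasible set:
    drop edges whose target anchor is unlabeled, deactivate anchors left
    without a THEME, iterate to a fixpoint; then activate every positively
    scoring witnessed binding pair."""
    labels = dict(e_map)
    edges = set(a_set)
    changed = True
    while changed:
        changed = False
        ok_edges = set()
        for (i, j, r) in edges:
            if i not in labels:
                changed = True
                continue
            if r == CAUSE and labels[i] not in inv.cause_licensed_types:
                changed = True
                continue
            if j not in proteins and j not in labels:
                changed = True
                continue
            ok_edges.add((i, j, r))
        edges = ok_edges
        for i in list(labels):
            if not any(s == i and r == THEME for (s, _t, r) in edges):
                del labels[i]
                changed = True
    b = set()
    for key, s in sB.items():
        if s <= 0:
            continue
        p, q = sorted(key)
        witnessed = any(
            labels.get(i) in inv.binding_types
            and (i, p, THEME) in edges
            and (i, q, THEME) in edges
            for i in labels
        )
        if witnessed:
            b.add(key)
    return JointAssignment(
        e=frozenset(labels.items()), a=frozenset(edges), b=frozenset(b)
    )


def infer_dd(
    inst: SentenceInstance,
    sT: dict,
    sR: dict,
    sB: dict,
    inventory: TypeInventory,
    max_iter: int = 100,
    eta0: float = 1.0,
):
    """Dual-decomposition inference.

    Returns ``(assignment, certificate, info)``.  The certificate is
    OPTIMAL when the best feasible primal score matches the dual bound to
    1e-9 (guaranteed optimal); otherwise HEURISTIC, returning the best
    constraint-repaired outgoing-subproblem solution seen.
    """
    anchors = inst.anchors
    proteins = inst.proteins
    prot_set = set(proteins)
    labels = inventory.all_types
    if not anchors:
        return JointAssignment.empty(), OPTIMAL, {"iterations": 0, "dual": 0.0, "primal": 0.0}

    u = {k: 0.0 for k in sT}
    v = {k: 0.0 for k in sR}
    lam = {k: 0.0 for k in sB}

    best_primal = -math.inf
    best_assign = JointAssignment.empty()
    best_dual = math.inf
    prev_dual = None
    n_increases = 0
    it = 0
    for it in range(1, max_iter + 1):
        adjT1 = {k: 0.5 * s + u[k] for k, s in sT.items()}
        adjT2 = {k: 0.5 * s - u[k] for k, s in sT.items()}
        adjR1 = {k: 0.5 * s + v[k] for k, s in sR.items()}
        adjR2 = {k: 0.5 * s - v[k] for k, s in sR.items()}

        out_sol = {}
        dual = 0.0
        for i in anchors:
            sol = _solve_outgoing(i, labels, inventory, anchors, proteins, adjT1, adjR1, lam)
            out_sol[i] = sol
            dual += sol[0]
        in_sol = {}
        for j in anchors + proteins:
            sol = _solve_incoming(
                j, j not in prot_set, labels, [i for i in anchors if i != j], adjT2, adjR2
            )
            in_sol[j] = sol
            dual += sol[0]
        b3 = {}
        for key, s in sB.items():
            val = s - lam[key]
            b3[key] = 1 if val > 0 else 0
            dual += max(val, 0.0)

        best_dual = min(best_dual, dual)

        # primal candidate from the outgoing solution
        e1 = {i: sol[1] for i, sol in out_sol.items() if sol[1] is not None}
        a1 = set().union(*[sol[2] for sol in out_sol.values()]) if out_sol else set()
        cand = _repair(e1, a1, inventory, prot_set, sB)
        primal = score_assignment(cand, sT, sR, sB)
        if primal > best_primal:
            best_primal = primal
            best_assign = cand

        if best_primal >= best_dual - 1e-9:
            return best_assign, OPTIMAL, {
                "iterations": it, "dual": best_dual, "primal": best_primal,
            }

        # subgradient step
        if prev_dual is not None and dual > prev_dual + 1e-12:
            n_increases += 1
        prev_dual = dual
        eta = eta0 / (1.0 + n_increases)

        e2 = {j: sol[1] for j, sol in in_sol.items() if sol[1] is not None}
        a2 = set().union(*[sol[2] for sol in in_sol.values()]) if in_sol else set()
        for (i, t) in sT:
            g = (1 if e1.get(i) == t else 0) - (1 if e2.get(i) == t else 0)
            if g:
                u[(i, t)] -= eta * g
        for k in sR:
            g = (1 if k in a1 else 0) - (1 if k in a2 else 0)
            if g:
                v[k] -= eta * g
        for key in sB:
            p, q = sorted(key)
            witnesses = sum(1 for sol in out_sol.values() if key in sol[3])
            g = witnesses - b3[key]
            if g:
                lam[key] = max(0.0, lam[key] - eta * g)

    return best_assign, HEURISTIC, {
        "iterations": it, "dual": best_dual, "primal": best_primal,
    }


# ---------------------------------------------------------------------------
# MIRA learning


def hamming_loss(gold: JointAssignment, pred: JointAssignment) -> int:
    return (
        len(gold.e ^ pred.e) + len(gold.a ^ pred.a) + len(gold.b ^ pred.b)
    )


def mira_update(
    w: Weights,
    gold: JointAssignment,
    pred: JointAssignment,
    scored: ScoredInstance,
    C: float = 0.1,
) -> float:
    """Single-constraint MIRA step.

    If the gold structure already wins by the loss-scaled margin, no
    change; otherwise w moves by tau * (Phi(gold) - Phi(pred)) with
    tau = min(C, (loss - margin) / ||Phi(gold) - Phi(pred)||^2).
    Returns the step size tau actually applied.
    """
    loss = hamming_loss(gold, pred)
    if loss == 0:
        return 0.0
    fg = scored.assignment_features(gold)
    fp = scored.assignment_features(pred)
    diff: dict[str, float] = dict(fg)
    for k, val in fp.items():
        diff[k] = diff.get(k, 0.0) - val
    diff = {k: val for k, val in diff.items() if val}
    margin = w.dot(fg) - w.dot(fp)
    if margin >= loss:
        return 0.0
    norm2 = sum(val * val for val in diff.values())
    if norm2 == 0:
        return 0.0  # identical features with positive loss: skip
    tau = min(C, (loss - margin) / norm2)
    w.add(diff, tau)
    return tau


def gold_assignment(doc: EventDocument, tokens: list[Token]) -> JointAssignment:
    g = events_to_graph(doc, tokens)
    return JointAssignment(
        e=frozenset(g.labels.items()),
        a=frozenset(g.edges),
        b=frozenset(g.binding_pairs),
    )


@dataclass
class JointModel:
    """Trained joint extractor: weights plus its feature configuration."""

    weights: Weights
    fx: FeatureExtractor

    def predict(
        self,
        inst: SentenceInstance,
        stacked: list[StackedPrediction] | None = None,
        max_iter: int = 100,
    ):
        fx = self.fx.with_stacked(stacked) if stacked is not None else self.fx
        scored = ScoredInstance(inst, fx)
        sT, sR, sB = scored.scores(self.weights, averaged=True)
        return infer_dd(inst, sT, sR, sB, fx.inventory, max_iter=max_iter)


def train(
    instances: list[SentenceInstance],
    stacked_predictions: dict[str, list[StackedPrediction]] | None,
    inventory: TypeInventory,
    epochs: int = 10,
    C: float = 0.1,
    seed: int = 0,
    stack_mode: str | None = "both",
    conjoin: bool = False,
    max_iter: int = 100,
) -> JointModel:
    """Train with 1-best MIRA; deterministic given the seed.

    ``stacked_predictions`` maps doc_id to the stacked systems' predictions
    for that document (empty/None = no stacking).  Returns a model holding
    averaged weights.
    """
    if not instances:
        raise ValueError("empty training corpus")
    rng = random.Random(seed)
    base_fx = FeatureExtractor(inventory, None, stack_mode=stack_mode, conjoin=conjoin)
    scored_cache: list[ScoredInstance] = []
    for inst in instances:
        preds = (stacked_predictions or {}).get(inst.doc_id) or []
        fx = FeatureExtractor(
            inventory, preds, stack_mode=stack_mode, conjoin=conjoin
        )
        if inst.gold is None:
            raise ValueError(f"instance {inst.doc_id} has no gold assignment")
        scored_cache.append(ScoredInstance(inst, fx))

    w = Weights()
    order = list(range(len(instances)))
    for _epoch in range(epochs):
        rng.shuffle(order)
        for idx in order:
            scored = scored_cache[idx]
            inst = scored.inst
            w.tick()
            sT, sR, sB = scored.scores(w)
            # Hamming-augmented decoding: each variable disagreeing with gold
            # gains +1, so the update targets the highest-scoring margin
            # violator rather than only outright prediction errors.
            gold = inst.gold
            aT = {k: s + (-1.0 if k in gold.e else 1.0) for k, s in sT.items()}
            aR = {k: s + (-1.0 if k in gold.a else 1.0) for k, s in sR.items()}
            aB = {k: s + (-1.0 if k in gold.b else 1.0) for k, s in sB.items()}
            pred, _cert, _info = infer_dd(
                inst, aT, aR, aB, inventory, max_iter=max_iter
            )
            mira_update(w, gold, pred, scored, C=C)
    return JointModel(weights=w, fx=base_fx)
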