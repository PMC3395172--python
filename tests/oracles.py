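"""Independent brute-force oracles shared by the test suite and the
acceptance script.

These deliberately re-derive every quantity by exhaustive enumeration —
label/edge-subset enumeration for joint inference, head-map enumeration
for tree decoding, argument-permutation search for event matching — and
never call the code paths they check.
"""

import random
from itertools import combinations, permutations, product

from bioevents.depparse import ARG_ROLES, ROOT, ROOT_ROLE, DependencyTree, TreeNode
from bioevents.graph import CANDIDATE_ANCHOR, PROTEIN, Token
from bioevents.joint import SentenceInstance
from bioevents.matching import APPROXIMATE, spans_match
from bioevents.standoff import CAUSE, THEME, Span


# ---------------------------------------------------------------------------
# joint inference


def random_instance(rng: random.Random, n_anchors: int, n_prot: int) -> SentenceInstance:
    kinds = [CANDIDATE_ANCHOR] * n_anchors + [PROTEIN] * n_prot
    rng.shuffle(kinds)
    toks = []
    pos = 0
    for i, k in enumerate(kinds):
        w = f"t{i}"
        toks.append(Token(i, w, Span(pos, pos + len(w)), k))
        pos += len(w) + 1
    return SentenceInstance("x", toks)


def random_scores(rng, inst, labels, lo=-2.0, hi=2.0):
    sT = {(i, t): rng.uniform(lo, hi) for i in inst.anchors for t in labels}
    sR = {
        (i, j, r): rng.uniform(lo, hi)
        for i in inst.anchors
        for j in inst.proteins + [a for a in inst.anchors if a != i]
        for r in (THEME, CAUSE)
    }
    sB = {frozenset(pq): rng.uniform(lo, hi) for pq in combinations(inst.proteins, 2)}
    return sT, sR, sB


def brute_force_optimum(inst, sT, sR, sB, inv) -> float:
    """Exhaustive maximization over the feasible set: enumerate label
    combinations and per-anchor protein-THEME subsets; remaining edges
    decompose per edge and binding pairs follow from witnesses."""
    labels = inv.all_types
    anchors = inst.anchors
    prots = sorted(inst.proteins)
    best = 0.0
    for lab_combo in product(*[[None] + list(labels) for _ in anchors]):
        lab = {a: t for a, t in zip(anchors, lab_combo) if t is not None}
        per_anchor = []
        feasible = True
        for a in anchors:
            t = lab.get(a)
            if t is None:
                per_anchor.append([(0.0, frozenset())])
                continue
            licensed = t in inv.cause_licensed_types
            binding = t in inv.binding_types
            targets = [j for j in lab if j != a]  # labeled anchors only
            indep = 0.0
            has_pos_theme = False
            for j in targets:
                if sR[(a, j, THEME)] > 0:
                    indep += sR[(a, j, THEME)]
                    has_pos_theme = True
            if licensed:
                for j in targets + prots:
                    indep += max(sR[(a, j, CAUSE)], 0.0)
            opts = []
            for mask in range(1 << len(prots)):
                psub = [prots[k] for k in range(len(prots)) if mask >> k & 1]
                sc = sT[(a, t)] + indep + sum(sR[(a, p, THEME)] for p in psub)
                if not psub and not has_pos_theme:
                    cand = [sR[(a, j, THEME)] for j in targets]
                    if not cand:
                        continue
                    sc += max(cand)
                pairs = (
                    frozenset(frozenset(pq) for pq in combinations(psub, 2))
                    if binding
                    else frozenset()
                )
                opts.append((sc, pairs))
            if not opts:
                feasible = False
                break
            per_anchor.append(opts)
        if not feasible:
            continue
        for combo in product(*per_anchor):
            sc = sum(o[0] for o in combo)
            witnessed = frozenset().union(*[o[1] for o in combo])
            sc += sum(sB[k] for k in witnessed if sB[k] > 0)
            best = max(best, sc)
    return best


# ---------------------------------------------------------------------------
# tree decoding


def random_scored_nodes(rng: random.Random, max_n: int = 5):
    n = rng.randint(2, max_n)
    nodes = sorted(rng.sample(range(9), n))
    scores = {}
    for d in nodes:
        scores[(ROOT, d, ROOT_ROLE)] = rng.uniform(-2, 2)
        for h in nodes:
            if h != d:
                for r in ARG_ROLES:
                    scores[(h, d, r)] = rng.uniform(-2, 2)
    return nodes, scores


def brute_force_trees(nodes, scores, projective: bool):
    """All spanning head-maps, acyclicity-checked, best role per slot."""
    best_val, best_heads = float("-inf"), None
    options = {d: [ROOT] + [h for h in nodes if h != d] for d in nodes}
    for combo in product(*[options[d] for d in nodes]):
        heads = dict(zip(nodes, combo))
        ok = True
        for d in nodes:
            seen, x = set(), d
            while x != ROOT and ok:
                if x in seen:
                    ok = False
                seen.add(x)
                x = heads[x]
        if not ok:
            continue
        total = 0.0
        hmap = {}
        for d, h in heads.items():
            if h == ROOT:
                s, r = scores[(ROOT, d, ROOT_ROLE)], ROOT_ROLE
            else:
                s, r = max(
                    ((scores[(h, d, rr)], rr) for rr in ARG_ROLES),
                    key=lambda x: (x[0], x[1] == THEME),
                )
            total += s
            hmap[d] = (h, r)
        if projective:
            t = DependencyTree({i: TreeNode(i, "X") for i in nodes}, hmap)
            if t.crossing_count() > 0:
                continue
        if total > best_val + 1e-12:
            best_val, best_heads = total, hmap
    return best_val, best_heads


# ---------------------------------------------------------------------------
# event matching


def oracle_match(pred, gold, policy, pred_doc, gold_doc, nested=False) -> bool:
    """Independent matcher: exhaustive bijection search over full argument
    permutations (no role grouping, no set-collapsing shortcuts)."""
    if pred.event_type != gold.event_type:
        return False
    pt = pred_doc.trigger_by_id()[pred.trigger_id]
    gt = gold_doc.trigger_by_id()[gold.trigger_id]
    if not spans_match(pt.span, gt.span, gold_doc.text, policy.span_slack):
        return False
    core_only = nested and policy.recursive_mode == APPROXIMATE

    def args_of(e, doc):
        sel = [(r, t) for (r, t) in e.args if not core_only or r == THEME]
        seen, out = set(), []
        prots = doc.protein_by_id()
        for r, t in sel:  # duplicate protein targets collapse
            key = (r, (prots[t].type, prots[t].span) if t in prots else t)
            if t in prots and key in seen:
                continue
            seen.add(key)
            out.append((r, t))
        return out

    pa = args_of(pred, pred_doc)
    ga = args_of(gold, gold_doc)
    if len(pa) != len(ga):
        return False
    p_prots = pred_doc.protein_by_id()
    g_prots = gold_doc.protein_by_id()
    for perm in permutations(range(len(ga))):
        ok = True
        for k, (pr, ptgt) in enumerate(pa):
            gr, gtgt = ga[perm[k]]
            if pr != gr or (ptgt in p_prots) != (gtgt in g_prots):
                ok = False
                break
            if ptgt in p_prots:
                pp, gp = p_prots[ptgt], g_prots[gtgt]
                if (pp.type, pp.span) != (gp.type, gp.span):
                    ok = False
                    break
            elif not oracle_match(
                pred_doc.event_by_id()[ptgt], gold_doc.event_by_id()[gtgt],
                policy, pred_doc, gold_doc, nested=True,
            ):
                ok = False
                break
        if ok:
            return True
    return False
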