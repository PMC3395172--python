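"""Non-projectivity (crossing-edge) analysis of token graphs.

A token graph is projective when it can be drawn above the sentence
without two edges crossing; non-projectivity is quantified as the number
of crossing edge pairs.  Two edges cross when, written as intervals over
token positions, they strictly interleave: min(a,b) < min(c,d) < max(a,b)
< max(c,d).  Self-loops and edge pairs sharing an endpoint never cross.
These counts drive the document-wise model comparison: documents are
partitioned into projective (zero gold crossings) and non-projective, and
per-document matched-event differences between two models are summarized
per partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import TokenGraph
from .matching import MatchPolicy, matched_event_count
from .standoff import EventDocument


def crossing_count(g: TokenGraph) -> int:
    """Number of crossing edge pairs, summed per sentence.

    Invariant under edge direction reversal and role labels; 0 iff the
    graph is projective.
    """
    sent = {t.index: t.sentence for t in g.tokens}
    intervals: list[tuple[int, int, int]] = []
    for (i, j, _r) in g.edges:
        if i == j:
            continue
        s = sent.get(i, 0)
        if sent.get(j, 0) != s:
            continue  # edges never span sentences in either model
        intervals.append((min(i, j), max(i, j), s))
    intervals = sorted(set(intervals))
    count = 0
    for a in range(len(intervals)):
        lo1, hi1, s1 = intervals[a]
        for b in range(a + 1, len(intervals)):
            lo2, hi2, s2 = intervals[b]
            if s1 != s2:
                continue
            if len({lo1, hi1, lo2, hi2}) < 4:
                continue  # shared endpoint
            if lo1 < lo2 < hi1 < hi2 or lo2 < lo1 < hi2 < hi1:
                count += 1
    return count


@dataclass
class ProjectivityReport:
    per_document: pd.DataFrame  # doc_id, gold_crossings, pred_crossings
    frac_docs_nonprojective: float
    frac_sentences_nonprojective: float
    frac_edges_crossing: float


def corpus_projectivity(graphs: dict[str, TokenGraph]) -> ProjectivityReport:
    """Corpus-level non-projectivity statistics of a set of token graphs."""
    rows = []
    nonproj_sents = 0
    n_sents = 0
    crossing_edges = 0
    n_edges = 0
    for doc_id in sorted(graphs):
        g = graphs[doc_id]
        c = crossing_count(g)
        rows.append({"doc_id": doc_id, "gold_crossings": c, "pred_crossings": c})
        sents = sorted({t.sentence for t in g.tokens}) or [0]
        n_sents += len(sents)
        for s in sents:
            sub = _sentence_subgraph(g, s)
            cs = crossing_count(sub)
            if cs > 0:
                nonproj_sents += 1
            crossing_edges += _edges_in_crossings(sub)
        n_edges += len(g.edges)
    df = pd.DataFrame(rows)
    n_docs = max(len(df), 1)
    return ProjectivityReport(
        per_document=df,
        frac_docs_nonprojective=float((df["gold_crossings"] > 0).mean()) if len(df) else 0.0,
        frac_sentences_nonprojective=nonproj_sents / max(n_sents, 1),
        frac_edges_crossing=crossing_edges / max(n_edges, 1),
    )


def _sentence_subgraph(g: TokenGraph, s: int) -> TokenGraph:
    sent = {t.index: t.sentence for t in g.tokens}
    return TokenGraph(
        tokens=g.tokens,
        labels={i: t for i, t in g.labels.items() if sent.get(i, 0) == s},
        edges={e for e in g.edges if sent.get(e[0], 0) == s and sent.get(e[1], 0) == s},
    )


def _edges_in_crossings(g: TokenGraph) -> int:
    """Number of distinct edges participating in at least one crossing."""
    intervals = sorted({(min(i, j), max(i, j)) for (i, j, _r) in g.edges if i != j})
    crossing = set()
    for a in range(len(intervals)):
        for b in range(a + 1, len(intervals)):
            lo1, hi1 = intervals[a]
            lo2, hi2 = intervals[b]
            if len({lo1, hi1, lo2, hi2}) < 4:
                continue
            if lo1 < lo2 < hi1 < hi2 or lo2 < lo1 < hi2 < hi1:
                crossing.add(intervals[a])
                crossing.add(intervals[b])
    return len(crossing)


def document_accuracy_diff(
    pred_a: dict[str, EventDocument],
    pred_b: dict[str, EventDocument],
    gold: dict[str, EventDocument],
    gold_graphs: dict[str, TokenGraph],
    policy: MatchPolicy,
) -> pd.DataFrame:
    """Per-document matched-event difference between two models.

    For each document: (#events of A matched with gold) minus (#events of
    B matched with gold), together with the document's gold crossing-arc
    count and its projective / non-projective partition.
    """
    ids = set(gold)
    if set(pred_a) - ids or set(pred_b) - ids or set(gold_graphs) != ids:
        raise KeyError("corpora must share doc_ids")
    rows = []
    for doc_id in sorted(ids):
        ma = matched_event_count(pred_a.get(doc_id), gold[doc_id], policy)
        mb = matched_event_count(pred_b.get(doc_id), gold[doc_id], policy)
        cx = crossing_count(gold_graphs[doc_id])
        rows.append(
            {
                "doc_id": doc_id,
                "matched_a": ma,
                "matched_b": mb,
                "diff": ma - mb,
                "gold_crossings": cx,
                "partition": "non-projective" if cx > 0 else "projective",
            }
        )
    return pd.DataFrame(rows)


def partition_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of matched-event differences per partition."""
    out = []
    for part, sub in df.groupby("partition"):
        q1, med, q3 = np.percentile(sub["diff"], [25, 50, 75]) if len(sub) else (0, 0, 0)
        out.append({"partition": part, "n_docs": len(sub), "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(out)
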