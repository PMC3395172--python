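"""Set-theoretic model combination, event origins, novel-event removal.

Two corrupted copies of one gold corpus play the two base systems.  Their
union trades precision for recall and their intersection the reverse.
Every event of a combined output is then classified by which base system
proposed it; events proposed by neither ("novel") are disproportionately
wrong, and removing them raises precision at a small recall cost.
"""

from bioevents import synth
from bioevents.combine import (
    classify_origins,
    combine_intersection,
    combine_union,
    origin_counts,
    remove_novel,
)
from bioevents.graph import ge_inventory
from bioevents.matching import STRICT_POLICY, score_corpus

inv = ge_inventory()
corpus = synth.generate(synth.GeneratorConfig(n_docs=120, seed=5), inv)
gold = synth.documents(corpus)
light = dict(anchor_miss=0.15, type_confusion=0.05, arc_miss=0.05)
a = synth.documents(synth.corrupt(corpus, synth.CorruptionConfig(**light, seed=6), inv))
b = synth.documents(synth.corrupt(corpus, synth.CorruptionConfig(**light, seed=7), inv))


def show(tag, pred):
    s = score_corpus(pred, gold, STRICT_POLICY, inv)["Overall"]
    print(f"{tag:>14}: P={s.precision:.3f} R={s.recall:.3f} F1={s.f1:.3f}")


show("system A", a)
show("system B", b)
show("union", combine_union(a, b, STRICT_POLICY))
show("intersection", combine_intersection(a, b, STRICT_POLICY))

# a combined output with planted novel events (proposed by neither base)
union = combine_union(a, b, STRICT_POLICY)
spiked = synth.documents(synth.inject_spurious(
    {d: (union[d], corpus[d][1]) for d in union}, rate=0.5, seed=8, inventory=inv))
origins = classify_origins(spiked, a, b, STRICT_POLICY)
counts = origin_counts(origins)
total = sum(counts.values())
print("\norigin classes of the combined output:")
for cls, n in counts.items():
    print(f"  {cls.value:>13}: {n:4d} ({n / total:.1%})")

show("with novel", spiked)
show("novel removed", remove_novel(spiked, a, b, STRICT_POLICY))
print("removing novel events raises precision and can only lower recall")
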