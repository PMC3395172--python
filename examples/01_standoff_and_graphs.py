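"""Parse a standoff document, project it to a token graph, and measure its
non-projectivity.

The example is the classic three-event sentence: a Phosphorylation of
TRAF2 is the CAUSE of a Regulation whose THEME is a TRAF2-CD40 Binding.
The CAUSE arc (inhibits -> phosphorylation) crosses the Binding THEME arc
(binding -> TRAF2), so the graph is non-projective with exactly one
crossing pair.
"""

from bioevents.graph import CANDIDATE_ANCHOR, PROTEIN, Token, ge_inventory, events_to_graph
from bioevents.projectivity import crossing_count
from bioevents.standoff import Span, read_document, write_document

TEXT = "the phosphorylation of TRAF2 inhibits binding to the CD40 cytoplasmic domain"
A1 = "T1\tProtein 23 28\tTRAF2\nT2\tProtein 53 57\tCD40\n"
A2 = """\
T3\tPhosphorylation 4 19\tphosphorylation
T4\tRegulation 29 37\tinhibits
T5\tBinding 38 45\tbinding
E1\tPhosphorylation:T3 Theme:T1
E2\tRegulation:T4 Theme:E3 Cause:E1
E3\tBinding:T5 Theme:T1 Theme2:T2
"""

TOKENS = [
    Token(0, "phosphorylation", Span(4, 19), CANDIDATE_ANCHOR),
    Token(1, "TRAF2", Span(23, 28), PROTEIN, ref_id="T1"),
    Token(2, "inhibits", Span(29, 37), CANDIDATE_ANCHOR),
    Token(3, "binding", Span(38, 45), CANDIDATE_ANCHOR),
    Token(4, "CD40", Span(53, 57), PROTEIN, ref_id="T2"),
]

doc = read_document(TEXT, A1, A2, doc_id="example")
print(f"parsed {len(doc.events)} events over {len(doc.proteins)} proteins:")
for e in doc.events:
    print(f"  {e.id} {e.event_type}: {e.args}")

g = events_to_graph(doc, TOKENS)
print(f"\ntoken-graph labels: {g.labels}")
print(f"edges: {sorted(g.edges)}")
print(f"binding pairs: {[sorted(p) for p in g.binding_pairs]}")
print(f"crossing arc pairs: {crossing_count(g)}  (1 = the CAUSE arc interleaves)")

a1, a2 = write_document(doc)
print("\nre-serialized .a2 (ids renumbered topologically, Theme2 restored):")
print(a2)
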