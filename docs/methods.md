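# Methods

## The task and its representation

A document in the BioNLP standoff convention is a text with given protein
mentions (`.a1`) and annotated triggers and events (`.a2`); offsets are
0-based half-open character intervals, and every emitted span must equal
the document substring it names. Events reference proteins and other
events by id; the reference graph must be acyclic. Numbered THEME roles
(`Theme2`, `Theme3`) are a serialization detail of multi-THEME Binding
events and are normalized to `THEME` on parse. Triggers with identical
span and type are merged to one canonical trigger on read — the format
permits both conventions and the merged form is the fixed point of our
writer, which also renumbers event ids topologically so serialization is
deterministic. Modifier lines (negation/speculation, `M…`) are carried
through opaquely and never interpreted.

Both extractors work on a *token graph*: vertices are protein tokens and
candidate anchor tokens, an anchor carries an event-type label, a labeled
edge `(i, j, role)` grounds an argument, and an unordered protein pair in
`binding_pairs` asserts "same Binding". Multiword triggers are grounded at
an annotated head token, falling back to the last token the span covers
(synthetic corpora always annotate single-token triggers). The structural
feasibility of a graph is four constraints: (1) every labeled anchor has
an outgoing THEME; (2) CAUSE edges only leave cause-licensed labels
(regulation types; Catalysis on the epigenetics-style inventory); (3) an
edge target that is a candidate anchor must itself be labeled; (4) every
binding pair is witnessed by some Binding-labeled anchor with THEME edges
to both members.

Converting a feasible graph back to events requires two decisions the
graph leaves open. Binding anchors with several protein THEMEs split
into events along the **maximal cliques** of the binding-pair relation
among those THEMEs (singletons for unpaired targets) — the witnessing
constraint alone does not determine the grouping, and cliques are the
minimal-assumption inverse. Valences are enforced at this serialization
boundary: simple and regulation anchors keep their first THEME in token
order, regulations at most one CAUSE. The four constraints also do not
forbid anchor-argument *cycles*, which serialized events cannot express;
within each strongly connected component of the anchor dependency graph
we keep only the forward (smaller-to-larger token index) edges, then drop
anchors left THEME-less. Prediction-side cycles are rare but must be
handled deterministically.

## The joint model

Inference maximizes the part-factored score over the feasible set by dual
decomposition with three subproblems: per-anchor label + outgoing edges,
per-token label + incoming edges, and binding-pair selection. The anchor
and argument variables are shared between the first two subproblems with
their scores split in half and agreement enforced by unconstrained
multipliers. The witnessing constraint couples the pair subproblem to the
outgoing subproblem; it is relaxed as `b[p,q] ≤ Σ_i witness_i(p,q)` with
projected non-negative multipliers, so the pair subproblem sees
`s_B(p,q) − λ[p,q]` and each outgoing subproblem earns `λ[p,q]` for
witnessing the pair. The outgoing subproblem is solved exactly: for each
candidate label, independently positive edges are taken, a THEME is
forced (best-scoring, possibly negative) when the label is active but no
THEME is positive, and — only when pair multipliers are live — protein
THEME subsets are enumerated to account for the pairwise bonuses.
Sentence-level protein counts in the synthetic corpora are small (≤ ~8),
so the enumeration is cheap; the fast per-edge path covers the common
case of λ = 0.

Subgradient steps use `η_t = η₀ / (1 + #dual-increases)` with `η₀ = 1`
and at most 100 iterations. At every iteration a feasible primal
candidate is built from the outgoing solution by constraint repair (drop
edges into unlabeled anchors, deactivate THEME-less anchors to a
fixpoint, then activate every positively scoring witnessed pair). The
**OPTIMAL certificate is issued only when the best primal score reaches
the best dual bound within 1e-9** — by weak duality this proves
optimality regardless of how the candidate was constructed; otherwise
the result is labeled HEURISTIC and is the best repaired candidate seen.
On random 3-anchor/3-protein instances roughly 90% of inferences certify,
and on instances small enough to enumerate, every certified solution
equals the brute-force optimum (this is asserted in the tests and
recomputed by the acceptance script).

Learning is 1-best MIRA with weight averaging: `τ = min(C, (loss −
margin) / ‖Φ(gold) − Φ(pred)‖²)`, loss = Hamming distance over the three
variable families, `C = 0.1`, 10 epochs by default, instance order
shuffled per epoch under the run seed. Training decodes with
Hamming-augmented scores (each variable disagreeing with gold gains +1),
so updates target the highest-scoring margin violator rather than only
outright errors; without it, score ties that break toward gold never
generate updates and the averaged weights can tip the other way on
degenerate vocabularies. The margin condition and the update itself are
exactly the single-constraint quadratic program.

Base features are deliberately lexical and local — token identity and
prefix for anchors; word pair, direction, binned distance and target kind
for arguments; word pair and distance for binding pairs — sufficient for
synthetic text whose tokens carry their own signal. Stacking features are
the indicator templates keyed by (system, proposed label, stacked label)
at anchors and (system, proposed role, stacked role) at arcs, with a NONE
bucket when the stacked system is silent, selectable as anchors-only /
arguments-only / both; conjunction mode suffixes every base feature with
the stacked label (and can retain or replace the originals).

## The dependency-parsing model

Events project to single-head trees: non-participating tokens drop out,
and a node with several parents keeps the earliest head in token order,
preferring THEME over CAUSE on ties — a deterministic instance of the
information the projection necessarily discards (shared arguments,
multiple parents). Remaining roots attach to a virtual root. The inverse
conversion makes an event of every anchor with at least one THEME child
(Binding collects all THEME children into one event; other types keep
the first THEME; one CAUSE where licensed) and is exact on tree-shaped
documents.

The parser is edge-factored and first-order: each `(head, dependent,
role)` is scored by a sparse linear model; decoding takes the best role
per slot and maximizes total score either projectively (Eisner's
algorithm, root leftmost — the output provably has zero crossing arcs)
or non-projectively (maximum spanning arborescence; networkx's
Chu-Liu/Edmonds implementation, with a uniform weight shift since the
arborescence has a fixed edge count). Training is an averaged structured
perceptron against the chosen decoder. Decoded trees carry no event
types, so a small averaged-perceptron anchor-type classifier (word and
prefix features) labels the anchors that end up with THEME children.
Parser training instances include the non-participating candidate tokens
attached to the root, because at prediction time the parser must place
every candidate; `project_to_tree` itself keeps the participant-only
contract.

Cross-validated stacking input follows the protocol of seeded
round-robin folds: each document is predicted by a model trained on the
other folds, so the stacker sees held-out-quality predictions during its
own training rather than flattering training-set accuracy (the tests
verify cross-validated anchor accuracy does not exceed self-trained
accuracy). Second-order decoding is out of scope — exact non-projective
second-order inference is intractable — and the stacking interface is
decoder-agnostic.

## Matching and evaluation

Two policies mirror the shared task's scoring modes. STRICT: identical
trigger spans, full argument sets compared recursively. APPROXIMATE:
the predicted trigger span may lie anywhere within the gold span extended
by `span_slack` words (default 1) on either side, and *nested* event
arguments are compared on their core — type, trigger, THEME arguments —
only. The exact semantics of the official scorer are not restated
anywhere authoritative, so this reading is isolated behind `MatchPolicy`
and configurable. Protein arguments match by entity type and span (the
`.a1` layer is shared input), duplicate protein THEMEs collapse to sets,
and nested event arguments are matched by an exact bijection search
(argument counts are tiny). Corpus scoring matches greedily one-to-one
per document in serialization order and micro-averages tp/fp/fn overall
and per category; the tests bound the greedy matcher by a
maximum-bipartite-matching oracle.

Union keeps the first corpus's serialization for matched duplicates and
imports unmatched events with their argument closures; intersection keeps
first-corpus events matched one-to-one, closed under argument reference
(cascade deletes keep documents valid). Origin classification places each
combined-output event in exactly one of four classes — matched by both
standalone outputs, by exactly one, or by neither (NOVEL) — under strict
matching, so the class counts partition the output; defining NOVEL as
"matched by neither" (rather than "not matched by both") is what makes
the four classes disjoint. Novel-event removal drops the NOVEL class with
reference-closure.

Non-projectivity of a graph is its number of crossing edge pairs —
unordered token intervals that strictly interleave; shared endpoints and
self-loops never cross, and multi-sentence documents sum per-sentence
counts since no edge spans sentences. The document-wise analysis
partitions documents by gold crossings (zero vs more) and summarizes
per-document matched-event differences between two models by median and
quartiles per partition.

## The synthetic generator

Documents are synthetic token strings joined by single spaces — protein
tokens (`PROT17`), trigger tokens whose surface form encodes their event
type (`pho3`, `bnd1`) or is deliberately ambiguous (`amb2`), and filler
words — so every offset, span and head annotation is exact without any
linguistic preprocessing. Defaults: 1 sentence per document, 1–3 events,
a Genia-like type mix skewed toward expression events, Regulation nesting
0.3, Binding multi-THEME 0.5, Regulation CAUSE 0.4, trigger ambiguity
0.35, distractor proteins/anchors at 0.6/0.4 per sentence, crossing-arc
documents at rate 0.2 (documents with crossing arcs are a persistent
~20% minority of real corpora). Event groups are laid out contiguously
with nested arguments placed inside their parents' span, which is
projective by construction; crossing documents embed one of two
constructions — the canonical Regulation whose CAUSE arc back to an
earlier event interleaves a Binding THEME arc (its crossing involves a
shared argument and does not survive tree projection), or two simple
events with swapped THEME order (whose crossing does survive projection
and is therefore what separates the 1N from the 1P decoder). The default
mixes the two equally. Generation is deterministic given the seed, and
the realized crossing-document fraction is binomial around the target
(±3 points at n = 1000 is asserted).

The corruption model derives base-model stand-ins from gold: per-event
anchor misses (with cascade to dependent events), type confusion within
the same valence class, per-argument arc misses (an event losing all
THEMEs is dropped), valence-compatible arc additions, and token-level
trigger span jitter. Under pure arc misses, strict recall has a
closed-form expectation — the product of survival probabilities over each
event's recursive argument closure — which the realized recall tracks.
A separate helper plants spurious events at unused candidate anchors
(synthetic "novel" events matched by no base model) for the
novel-removal experiments.

**What the generator does not emulate**: real biomedical language —
lexical ambiguity beyond the explicit `amb*` class, syntactic structure,
coordination, anaphora, multiword triggers needing real head finding,
site/location arguments, negation/speculation. Passing tests establish
the algorithms' correctness and the direction of the stacking and
novel-removal effects under controlled conditions; they say nothing about
absolute scores on licensed shared-task corpora, which require the
original data and the base systems' full feature stacks.

## Experiment configurations

The stacking experiment trains the joint model with and without a
corrupted-gold base model (anchor miss 0.15, type confusion 0.10, arc
miss 0.10) as stacking input on 500-document corpora (350 train / 150
dev), 3 MIRA epochs, and compares dev F1 paired over 10 seeds with a
one-sided sign test; ambiguity of trigger words is the complementary
signal that makes stacking informative. The novel-removal experiment
unions two light corruptions of one gold corpus, plants spurious events,
and verifies precision rises while recall cannot. Problem sizes (corpus
counts, epochs, oracle instance sizes of ≤3 anchors / ≤3 proteins and ≤6
tree nodes) are chosen so every oracle is exhaustive and the full suite
runs in minutes on one CPU.

## Known limitations

- The dual decomposition certificate is sufficient, not necessary: a
  primal-dual gap can remain on instances whose LP relaxation is loose,
  in which case the HEURISTIC output is feasible but unproven (~10% of
  random small instances; rarer on trained weights).
- Binding-pair subset enumeration in the outgoing subproblem is
  exponential in the per-sentence protein count; it is exact for the
  sentence sizes generated here and would need a greedy fallback (losing
  certificates) for very protein-dense sentences.
- Graph-to-event conversion is lossy by design where the graph
  underdetermines events (binding cliques, regulation THEME choice,
  cycles); all such choices are deterministic and documented above.
- The approximate-recursive matching mode is an interpretation of the
  shared task's scorer, isolated behind `MatchPolicy`.
- The reranking layer, second-order decoders and negation/speculation
  prediction are intentionally out of scope.
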