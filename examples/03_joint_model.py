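"""Train the joint extractor (dual decomposition + MIRA) and inspect its
inference certificates.

On a separable corpus (type-revealing trigger words, fixed argument
layout) the model fits the training data exactly; inference reports an
OPTIMAL certificate whenever the dual bound meets the best feasible
solution, which on these instances is nearly always.
"""

from bioevents import synth
from bioevents.graph import ge_inventory
from bioevents.matching import STRICT_POLICY
from bioevents.pipeline import evaluate, predict_joint, train_joint

inv = ge_inventory()
corpus = synth.generate(synth.separable_config(n_docs=60, seed=3), inv)

model = train_joint(corpus, None, inv, epochs=10, seed=3, stack_mode=None)
print(f"trained on {len(corpus)} documents; {len(model.weights.w)} features")

pred = predict_joint(model, corpus)
certs = list(pred.certificates.values())
print(f"OPTIMAL certificates: {certs.count('OPTIMAL')}/{len(certs)}")

scores = evaluate(pred.documents, synth.documents(corpus), STRICT_POLICY, inv)
for cat in ("Simple", "Binding", "Regulation", "Overall"):
    if cat in scores:
        s = scores[cat]
        print(f"{cat:>11}: P={s.precision:.3f} R={s.recall:.3f} F1={s.f1:.3f}")
print("F1 = 1.0 on every category: the separable conditions are fit exactly.")
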