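"""Simulate a two-class dataset, train the SVM, and call verdicts.

Hotspot and coldspot classes are separated by GC content (0.35 vs 0.65),
which the trinucleotide composition captures directly.
"""

from recspot import FixtureSpec, generate, predict, train
from recspot.classifier import HOTSPOT
from recspot.features import encode_many

spec = FixtureSpec(n_per_class=25, length_range=(300, 2000),
                   gc_hot=0.35, gc_cold=0.65, seed=3)
seqs, labels = generate(spec)

features = encode_many(seqs)                 # 50 x 69 matrix
model = train(features.to_numpy(), labels)   # defaults C=32, gamma=0.5
print(f"trained on {len(labels)} sequences; fingerprint {model.fingerprint}")

# score three held-out queries from a fresh draw
probe_spec = FixtureSpec(n_per_class=2, length_range=(300, 2000),
                         gc_hot=0.35, gc_cold=0.65, seed=99)
probes, truth = generate(probe_spec)
X = encode_many(probes).to_numpy()
for seq, true, (label, score) in zip(probes, truth, predict(model, X)):
    verdict = "recombination hotspot" if label == HOTSPOT else "recombination coldspot"
    print(f"{seq.id:10s} -> {verdict:22s} score={score:+.3f} "
          f"({'correct' if label == true else 'WRONG'})")
# Positive decision scores mean hotspot; magnitude reflects margin distance.
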