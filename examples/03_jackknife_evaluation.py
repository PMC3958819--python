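"""Jackknife (leave-one-out) evaluation with the four standard metrics.

Every sample is predicted by a model trained on all the others, so the
outcome is unique for a dataset — no fold-assignment randomness.
"""

from recspot import FixtureSpec, generate, jackknife, kfold
from recspot.features import encode_many

spec = FixtureSpec(n_per_class=20, length_range=(300, 1500),
                   gc_hot=0.35, gc_cold=0.65, seed=8)
seqs, labels = generate(spec)
X = encode_many(seqs).to_numpy()

result = jackknife(X, labels)          # fixed C=32, gamma=0.5 across folds
m, c = result.metrics, result.counts
print(f"jackknife over n={len(labels)}:")
print(f"  confusion  TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}")
print(f"  Sn={m.sn:.4f}  Sp={m.sp:.4f}  Acc={m.acc:.4f}  MCC={m.mcc:.4f}")

five = kfold(X, labels, folds=5, seed=0)
print(f"5-fold (seed 0): Acc={five.metrics.acc:.4f}  "
      "(cheaper, but fold-assignment dependent)")
# Sn: fraction of hotspots recovered; Sp: fraction of coldspots recovered;
# MCC balances both and is 0 at chance, 1 when perfect.
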