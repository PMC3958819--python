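"""Encode a single DNA sequence into the 64+lambda feature vector.

The first 64 components are the overlapping trinucleotide frequencies
(lexicographic order AAA..TTT); the last lambda components are the
weighted pseudo amino acid correlation tiers of the translated chain.
The whole vector sums to 1.
"""

import numpy as np

from recspot import NucleotideSequence, encode, translate_dna
from recspot.features import feature_names

seq = NucleotideSequence("demo", "ATGGCGTACGTTAGCGGCCATTAA" * 5)
prot = translate_dna(seq)
vec = encode(seq, lam=5, weight=1.1)

print(f"sequence length      : {seq.length} nt")
print(f"translated chain     : {prot.residues[:30]}... "
      f"(L*={prot.length}, {prot.n_stops_removed} stop codons removed)")
print(f"vector dimension     : {vec.shape[0]}  (64 trinucleotides + 5 tiers)")
print(f"component sum        : {vec.sum():.12f}  (simplex contract)")
top = np.argsort(vec[:64])[::-1][:3]
names = feature_names(5)
print("largest TNC entries  :",
      ", ".join(f"{names[i]}={vec[i]:.4f}" for i in top))
print("correlation tiers    :",
      ", ".join(f"{names[64 + k]}={vec[64 + k]:.4f}" for k in range(5)))
# The tier entries measure how physicochemically dissimilar residues k
# positions apart are, relative to the composition signal.
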