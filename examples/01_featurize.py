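"""Encode a peptide the way the classifier sees it.

Builds the two input blocks for one small protein: the padded one-hot
coding (20 entries per position over 100 positions = 2000 binary values)
and the gapped (4,2)-mer counts (400 ordered residue pairs with span <= 4).
"""

import numpy as np

from pspi import NkSpec, assemble_features, count_nk_mers, onehot_encode
from pspi.features import AA_INDEX

# MgrB-like toy peptide: a 20-residue small protein fragment
peptide = "MKKFRWVVLGVVVLACFLLW"

onehot = onehot_encode(peptide)
print(f"peptide: {peptide} ({len(peptide)} AA)")
print(f"one-hot block: {onehot.shape[0]} entries, {int(onehot.sum())} ones")
print("  (one 1 per residue; positions beyond the peptide stay zero)")

dimers = count_nk_mers(peptide, NkSpec(4, 2))
print(f"(4,2)-mer block: {dimers.shape[0]} entries, "
      f"{int(dimers.sum())} pair occurrences counted")

# the most frequent gapped pairs in this peptide
aa = "ACDEFGHIKLMNPQRSTVWY"
top = np.argsort(dimers)[::-1][:5]
print("top gapped pairs (residue pair: occurrences within span 4):")
for flat in top:
    a, b = divmod(int(flat), 20)
    print(f"  {aa[a]}..{aa[b]}: {int(dimers[flat])}")

fv = assemble_features(peptide)
print(f"full feature vector: {fv.values.shape[0]} = 2000 one-hot + 400 counts")
# e.g. the V..V pair is abundant in this Val-rich stretch
vv = dimers[AA_INDEX["V"] * 20 + AA_INDEX["V"]]
print(f"V..V occurrences within span 4: {int(vv)}")
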