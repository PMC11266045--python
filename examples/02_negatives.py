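"""Build the two null-sequence classes from scratch.

Shows (1) a permuted-ORF negative: synonymous back-translation, shuffle of
the internal nucleotides with the first and stop codons fixed, stop repair,
re-translation; and (2) noncoding-RNA negatives: random fragments of an
RNA pool translated in frame 0 after stop replacement.
"""

import numpy as np

from pspi import NucRecord, permute_peptide, rna_to_negatives

rng = np.random.default_rng(42)

source = "MKKFRWVVLGVVVLACFLLW"
res = permute_peptide(source, rng)
print(f"source peptide : {source}")
print(f"permuted ORF   : {res.nucleotide.seq}")
print(f"permuted pep   : {res.peptide}")
print(f"stop repairs   : {res.n_stop_repairs}")
print("  (same length, same first residue, different residue composition:")
print("   the shuffle acts on nucleotides, so codons are rebuilt from the")
print("   same nucleotide pool rather than re-ordered)")

# a synthetic noncoding-RNA pool: 5 kb of random nucleotides
rna = NucRecord("pool", "".join(np.array(list("ACGT"))[rng.integers(4, size=5000)]))
batch = rna_to_negatives([rna], rng=rng)
print(f"\nRNA pool of {len(rna.seq)} nt partitioned into "
      f"{len(batch.peptides)} fragments")
print(f"fragment lengths: {min(batch.fragment_lengths)}-"
      f"{max(batch.fragment_lengths)} nt (bounds 30-300)")
print(f"peptide lengths : {min(map(len, batch.peptides))}-"
      f"{max(map(len, batch.peptides))} AA (bounds 10-100)")
print(f"first pseudo-peptide: {batch.peptides[0]}")
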