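"""Null-sequence generators: permuted ORFs and noncoding-RNA pseudo-peptides.

Two negative classes are produced, matching the two failure modes a
small-protein classifier must reject:

* **Permuted-ORF negatives** — a peptide is back-translated with random
  synonymous codons, a stop codon is appended, the nucleotides strictly
  between the first codon and the final stop are uniformly shuffled, any
  internal in-frame stop codon is replaced by a random sense codon, and the
  result is re-translated.  Shuffling at the nucleotide level (not the
  amino-acid level) deliberately changes the amino-acid composition: a mere
  residue permutation would share the source's composition and could still
  be a real small protein.

* **Noncoding-RNA negatives** — noncoding RNA sequences are concatenated
  and partitioned left-to-right into non-overlapping fragments of 30-300
  nt; in-frame stop codons are replaced with random sense codons and each
  fragment is translated in frame 0, yielding stop-free pseudo-peptides of
  10-100 residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pspi.seqio import (
    NucRecord,
    SENSE_CODONS,
    STANDARD_TABLE,
    STOP_CODONS,
    back_translate,
    translate,
)

_STOPS = tuple(sorted(STOP_CODONS))


@dataclass(frozen=True)
class PermutationResult:
    """A shuffled-ORF negative: peptide, its ORF, and the repair count."""

    peptide: str
    nucleotide: NucRecord
    n_stop_repairs: int


@dataclass(frozen=True)
class RnaNegativeBatch:
    """Pseudo-peptides translated from partitioned noncoding RNA."""

    peptides: list[str]
    fragment_lengths: list[int]
    seed: int | None = None


def _shuffle_and_repair(
    nuc_with_stop: str, rng: np.random.Generator
) -> tuple[str, int]:
    """Shuffle internal nucleotides, repair internal stops, keep ends fixed.

    ``nuc_with_stop`` is a full ORF (first codon + body + stop codon).  The
    region strictly between the first codon and the final stop codon is
    permuted uniformly at the single-nucleotide level.  Any stop codon then
    found at an internal in-frame position is replaced by a codon drawn
    uniformly from the 61 sense codons; since replacements are sense
    codons, a single pass leaves no internal stop.
    """
    n = len(nuc_with_stop)
    head, internal, tail = nuc_with_stop[:3], nuc_with_stop[3 : n - 3], nuc_with_stop[n - 3 :]
    internal_arr = np.array(list(internal))
    rng.shuffle(internal_arr)
    codons = ["".join(internal_arr[i : i + 3]) for i in range(0, len(internal_arr), 3)]
    n_repairs = 0
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            codons[i] = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
            n_repairs += 1
    return head + "".join(codons) + tail, n_repairs


def permute_peptide(
    peptide: str, rng: np.random.Generator | None = None
) -> PermutationResult:
    """Build a permuted-ORF negative from a peptide sequence.

    Pipeline: random synonymous back-translation -> append a uniformly
    chosen stop codon -> uniform shuffle of the internal nucleotides (first
    codon and stop codon held fixed) -> replace internal stop codons with
    random sense codons -> translate.  Length and first residue of the
    source are conserved.
    """
    if not peptide:
        raise ValueError("cannot permute an empty peptide")
    if rng is None:
        rng = np.random.default_rng()
    nuc = back_translate(peptide, rng).seq
    stop = _STOPS[int(rng.integers(3))]
    shuffled, n_repairs = _shuffle_and_repair(nuc + stop, rng)
    new_pep = translate(shuffled[:-3], frame=0)
    return PermutationResult(
        peptide=new_pep,
        nucleotide=NucRecord("permuted", shuffled),
        n_stop_repairs=n_repairs,
    )


def permute_orf(
    orf: NucRecord, rng: np.random.Generator | None = None
) -> PermutationResult:
    """Permute an existing ORF directly (no back-translation step).

    The ORF must be a whole number of codons, at least two codons long, end
    with a stop codon, and contain no internal stop.
    """
    if rng is None:
        rng = np.random.default_rng()
    seq = orf.seq
    if len(seq) % 3 != 0:
        raise ValueError(
            f"ORF {orf.id!r}: length {len(seq)} is not a multiple of 3"
        )
    if len(seq) < 6:
        raise ValueError(f"ORF {orf.id!r}: fewer than 2 codons")
    if seq[-3:] not in STOP_CODONS:
        raise ValueError(
            f"ORF {orf.id!r}: does not end with a stop codon (got {seq[-3:]})"
        )
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise ValueError(
                f"ORF {orf.id!r}: internal stop codon at nucleotide {i}"
            )
    shuffled, n_repairs = _shuffle_and_repair(seq, rng)
    new_pep = translate(shuffled[:-3], frame=0)
    return PermutationResult(
        peptide=new_pep,
        nucleotide=NucRecord(orf.id, shuffled),
        n_stop_repairs=n_repairs,
    )


def rna_to_negatives(
    rna: list[NucRecord],
    min_len: int = 30,
    max_len: int = 300,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> RnaNegativeBatch:
    """Translate random fragments of noncoding RNA into pseudo-peptides.

    All input sequences are concatenated; fragment lengths are drawn
    uniformly on ``[min_len, max_len]`` walking left to right (clamped to
    what remains), and a final remainder shorter than ``min_len`` is
    discarded.  Each fragment is read in frame 0 with any trailing partial
    codon dropped; in-frame stop codons are replaced uniformly from the 61
    sense codons before translation.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    concat = "".join(r.seq for r in rna)
    if len(concat) < min_len:
        raise ValueError(
            f"total RNA length {len(concat)} nt is below min_len {min_len}"
        )
    peptides: list[str] = []
    fragment_lengths: list[int] = []
    pos = 0
    while len(concat) - pos >= min_len:
        hi = min(max_len, len(concat) - pos)
        frag_len = int(rng.integers(min_len, hi + 1))
        frag = concat[pos : pos + frag_len]
        pos += frag_len
        fragment_lengths.append(frag_len)
        n_codons = len(frag) // 3
        codons = [frag[3 * i : 3 * i + 3] for i in range(n_codons)]
        for i, codon in enumerate(codons):
            if codon in STOP_CODONS:
                codons[i] = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
        peptides.append(translate("".join(codons), frame=0))
    return RnaNegativeBatch(
        peptides=peptides, fragment_lengths=fragment_lengths, seed=seed
    )
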