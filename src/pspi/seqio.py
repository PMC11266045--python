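"""FASTA I/O, alphabet validation, translation and random back-translation.

Sequence records are thin, validated containers.  Peptides are restricted to
the 20 canonical amino-acid letters: the stop symbol ``*`` and the ambiguity
codes B, J, O, U, X, Z are rejected outright rather than skipped, because a
classifier trained on canonical residues has no defined input for them.
Nucleotide records are uppercase DNA; RNA input is accepted and ``U`` is
normalized to ``T`` on ingestion.

The codon table is NCBI translation table 1 (the standard code), taken from
Biopython.  Translation drops a terminal stop codon silently but treats an
internal stop as an error — repairing internal stops is the job of the
negative-sequence generators, not of this layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)
_NUC_SET = frozenset("ACGT")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FastaParseError(ValueError):
    """Malformed FASTA input."""


class SequenceValidationError(ValueError):
    """A sequence contains a character outside its declared alphabet."""


class TranslationError(ValueError):
    """Translation failed (internal stop codon or too-short frame)."""


@dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide over the 20 canonical amino-acid letters."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _AA_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: disallowed peptide character(s) "
                f"{sorted(bad)!r} (stop '*' and ambiguity codes B/J/O/U/X/Z "
                "are rejected)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NucRecord:
    """An identified DNA sequence over {A, C, G, T}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - _NUC_SET
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: disallowed nucleotide character(s) "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _build_tables() -> tuple[dict[str, str], dict[str, tuple[str, ...]]]:
    std = _BioCodonTable.unambiguous_dna_by_id[1]
    forward: dict[str, str] = dict(std.forward_table)
    for stop in std.stop_codons:
        forward[stop] = "*"
    backward: dict[str, list[str]] = {}
    for codon, aa in sorted(std.forward_table.items()):
        backward.setdefault(aa, []).append(codon)
    return forward, {aa: tuple(cods) for aa, cods in backward.items()}


@dataclass(frozen=True)
class CodonTable:
    """Standard codon table (NCBI table 1) with synonymous-codon lookup.

    ``forward`` maps every one of the 64 codons to an amino acid or ``'*'``;
    ``backward`` maps each amino acid to its nonempty tuple of synonymous
    codons (the 61 sense codons, partitioned); ``stops`` is {TAA, TAG, TGA}.
    """

    forward: dict[str, str] = field(default_factory=lambda: _build_tables()[0])
    backward: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: _build_tables()[1]
    )
    stops: frozenset[str] = STOP_CODONS


STANDARD_TABLE = CodonTable()

#: the 61 sense codons, in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(STANDARD_TABLE.forward) if c not in STOP_CODONS
)


def read_fasta(
    path: str | Path, alphabet: Literal["peptide", "nucleotide"]
) -> list[PeptideRecord] | list[NucRecord]:
    """Read a FASTA file into validated records, in file order.

    The record id is the full header line minus the leading ``>``.
    Sequences are uppercased; in nucleotide mode ``U`` is normalized to
    ``T``.  A disallowed character raises :class:`SequenceValidationError`
    naming the record and the offending symbol.
    """
    if alphabet not in ("peptide", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    _check_fasta_shape(path)
    records: list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        rec_id = rec.description  # full header minus '>'
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
            records.append(NucRecord(rec_id, seq))
        else:
            records.append(PeptideRecord(rec_id, seq))
    return records


def _check_fasta_shape(path: Path) -> None:
    # Bio.SeqIO silently yields nothing for a header-less file; fail loudly,
    # naming the first offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected '>' header, got "
                    f"{line[:30]!r}"
                )
            return  # first non-blank line is a header; good enough


def write_fasta(
    records: Iterable[PeptideRecord | NucRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records to ``path``; round-trips ids and sequences exactly."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def translate(
    nuc: NucRecord | str,
    frame: int = 0,
    table: CodonTable = STANDARD_TABLE,
) -> str:
    """Translate a DNA sequence in the given frame (0, 1 or 2).

    One residue per complete codon; a trailing partial codon is dropped.  A
    terminal stop codon is dropped silently; an internal stop raises
    :class:`TranslationError` with its codon position (callers must repair
    stops first).
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = nuc.seq if isinstance(nuc, NucRecord) else nuc
    body = seq[frame:]
    n_codons = len(body) // 3
    if n_codons < 1:
        raise TranslationError(
            f"in-frame length {len(body)} nt is shorter than one codon"
        )
    residues: list[str] = []
    for i in range(n_codons):
        codon = body[3 * i : 3 * i + 3]
        aa = table.forward[codon]
        if aa == "*":
            if i == n_codons - 1:
                break  # terminal stop dropped silently
            raise TranslationError(
                f"internal stop codon {codon} at codon position {i + 1}"
            )
        residues.append(aa)
    return "".join(residues)


def back_translate(
    peptide: str,
    rng: np.random.Generator | None = None,
    table: CodonTable = STANDARD_TABLE,
) -> NucRecord:
    """Back-translate a peptide, drawing each codon uniformly at random.

    Each residue with multiple synonymous codons gets one chosen uniformly
    from its set, so ``translate(back_translate(p)) == p`` for any valid
    peptide and any seed.  No stop codon is appended here.
    """
    if rng is None:
        rng = np.random.default_rng()
    codons: list[str] = []
    for pos, aa in enumerate(peptide):
        try:
            choices = table.backward[aa]
        except KeyError:
            raise SequenceValidationError(
                f"invalid residue {aa!r} at position {pos}"
            ) from None
        codons.append(choices[int(rng.integers(len(choices)))])
    return NucRecord("backtranslated", "".join(codons))
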