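"""Seeded synthetic datasets with planted gapped-dimer signal.

Real small-protein collections cannot ship with a package, so this module
generates desk-scale labeled data with the statistical structure the
classifier assumes: positive peptides carry an enrichment of short-span
residue pairs (a stand-in for the short linear motifs real small proteins
are thought to contain), while negatives are built by the package's own
null procedures — half by synonymous-codon permutation of the positives,
half by translating random noncoding-RNA fragments.  Everything is a pure
function of the seed, so datasets are regenerated at test time instead of
being committed.

What this emulates and what it does not: the planted-pair mechanism gives
positives a genuine order-dependent signal at the (n,k)-mer scale, and the
50/50 negative mix mirrors the observation that training against a single
negative source inflates error on the other.  It does not model real codon
usage bias, phylogenetic redundancy between sequences, or the length and
composition distributions of any particular taxon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pspi.negatives import permute_peptide, rna_to_negatives
from pspi.seqio import AMINO_ACIDS, NucRecord, PeptideRecord


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``planted_pairs`` is a list of (residue_a, residue_b, max_span)
    triples; walking the sequence left to right, each position starts a
    planted pair with probability ``enrichment_rate`` (pair chosen
    uniformly from the list, gap uniform within the span).  Rate 0 gives a
    pure-background no-signal control.
    """

    n_pos: int = 1000
    n_neg: int = 1000
    length_range: tuple[int, int] = (30, 100)
    planted_pairs: tuple[tuple[str, str, int], ...] = (("C", "D", 4),)
    enrichment_rate: float = 0.3
    composition: tuple[float, ...] = field(
        default_factory=lambda: tuple([1.0 / 20] * 20)
    )
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not 1 <= lo <= hi <= 100:
            raise ValueError("length_range must satisfy 1 <= lo <= hi <= 100")
        if not 0 <= self.enrichment_rate <= 1:
            raise ValueError("enrichment_rate must be in [0, 1]")
        if len(self.composition) != 20 or not np.isclose(
            sum(self.composition), 1.0
        ):
            raise ValueError("composition must be 20 probabilities summing to 1")
        for a, b, span in self.planted_pairs:
            if span < 2:
                raise ValueError(f"planted pair span must be >= 2, got {span}")
            if span > lo:
                raise ValueError(
                    f"planted span {span} exceeds the minimum length {lo}"
                )


@dataclass(frozen=True)
class LabeledSet:
    """Peptide sequences with binary labels (1 = small protein)."""

    records: list[PeptideRecord]
    labels: list[int]

    @property
    def peptides(self) -> list[str]:
        return [r.seq for r in self.records]


def gen_positives(
    config: SynthConfig,
    rng: np.random.Generator | None = None,
    id_prefix: str = "pos",
) -> list[PeptideRecord]:
    """Generate positives: 'M'-initial peptides with planted pair signal.

    Lengths are uniform over ``length_range``; residues are drawn from the
    background composition, then planted pairs overwrite positions at the
    configured per-position rate with gaps uniform in [1, max_span - 1].
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))
    comp = np.asarray(config.composition)
    lo, hi = config.length_range
    records = []
    for i in range(config.n_pos):
        L = int(rng.integers(lo, hi + 1))
        seq = list(aa[rng.choice(20, size=L, p=comp)])
        seq[0] = "M"
        if config.planted_pairs and config.enrichment_rate > 0:
            for pos in range(1, L - 1):
                if rng.random() < config.enrichment_rate:
                    a, b, span = config.planted_pairs[
                        int(rng.integers(len(config.planted_pairs)))
                    ]
                    gap = int(rng.integers(1, span))  # span = gap + 1 <= max
                    if pos + gap < L:
                        seq[pos] = a
                        seq[pos + gap] = b
        records.append(PeptideRecord(f"{id_prefix}_{i:05d}", "".join(seq)))
    return records


def _gen_negatives(
    positives: list[PeptideRecord],
    n_neg: int,
    rng: np.random.Generator,
    id_prefix: str,
) -> list[PeptideRecord]:
    """Half permuted-ORF negatives of the positives, half RNA-derived."""
    n_perm = n_neg // 2
    n_rna = n_neg - n_perm
    records = []
    src = rng.choice(len(positives), size=n_perm, replace=n_perm > len(positives))
    for j, si in enumerate(src):
        res = permute_peptide(positives[int(si)].seq, rng)
        records.append(PeptideRecord(f"{id_prefix}_perm_{j:05d}", res.peptide))
    # random "noncoding RNA" long enough to yield n_rna fragments of <= 300 nt
    total_nt = 310 * n_rna + 400
    rna_seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=total_nt)])
    batch = rna_to_negatives([NucRecord("synthetic_rna", rna_seq)], rng=rng)
    for j, pep in enumerate(batch.peptides[:n_rna]):
        records.append(PeptideRecord(f"{id_prefix}_rna_{j:05d}", pep))
    if len(records) < n_neg:
        raise RuntimeError("RNA pool too short for requested negatives")
    return records


def gen_dataset(
    config: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LabeledSet, LabeledSet]:
    """Generate disjoint (train, test) labeled sets.

    The training set has exactly ``n_pos`` positives and ``n_neg``
    negatives; the test set is generated from fresh source peptides
    (``test_fraction`` of the training counts), so no positive source
    peptide is shared between splits.  Negatives are a 50/50 mix of
    permuted positives and RNA-derived pseudo-peptides.
    """
    if config is None:
        config = SynthConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_test_pos = max(1, round(config.test_fraction * config.n_pos))
    n_test_neg = max(2, round(config.test_fraction * config.n_neg))

    def one_split(n_pos: int, n_neg: int, tag: str) -> LabeledSet:
        cfg = SynthConfig(
            n_pos=n_pos,
            n_neg=n_neg,
            length_range=config.length_range,
            planted_pairs=config.planted_pairs,
            enrichment_rate=config.enrichment_rate,
            composition=config.composition,
            test_fraction=config.test_fraction,
            seed=config.seed,
        )
        pos = gen_positives(cfg, rng, id_prefix=f"{tag}_pos")
        neg = _gen_negatives(pos, n_neg, rng, id_prefix=f"{tag}_neg")
        return LabeledSet(
            records=pos + neg, labels=[1] * len(pos) + [0] * len(neg)
        )

    return (
        one_split(config.n_pos, config.n_neg, "train"),
        one_split(n_test_pos, n_test_neg, "test"),
    )
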