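"""Input representations: padded one-hot coding and gapped (n,k)-mer counts.

An (n,k)-mer is an ordered k-tuple of residues occurring at positions
``i_1 < i_2 < ... < i_k`` whose total span ``i_k - i_1 + 1`` is at most
``n``; the gaps inside the span may fall anywhere.  The identity of the mer
is the residue tuple alone, not the gap arrangement — ``ACD``, ``AC.D`` and
``A.C.D`` are all the same (7,3)-mer, while ``A....C.D`` (span 8) is not a
(7,3)-mer.  This mimics short linear motifs: short, order-determined
functional patterns of 3-10 residues that live in unstructured protein
regions.

For k <= 2 tuples are counted over the plain 20-letter alphabet (dimension
20^k); for k > 2 the feature space would explode, so residues are first
mapped to 9 physicochemical groups (dimension 9^k).

Counting is by occurrence: every qualifying index tuple contributes one
count, not a binary presence flag.  Counts are raw integers by default; a
length-normalization switch exists but is off, which keeps the features
integer-exact and testable against exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from pspi.seqio import AMINO_ACIDS

#: residue -> ordinal 0..19, alphabetical over the one-letter codes
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Nine physicochemical groups. The acidic group is [DE]: aspartate and
# glutamate share charge and chemistry, and without E the nine groups would
# cover only 19 of the 20 canonical residues.
_DEGENERATE_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g) for g in ("AGILPV", "FW", "M", "C", "ST", "Y", "DE", "HKR", "NQ")
)


@dataclass(frozen=True)
class DegenerateAlphabet:
    """The 9-group physicochemical reduction of the 20 amino acids.

    Groups, in fixed order: [AGILPV], [FW], [M], [C], [ST], [Y], [DE],
    [HKR], [NQ].  They partition the 20 canonical residues.
    """

    groups: tuple[frozenset[str], ...] = _DEGENERATE_GROUPS
    index: dict[str, int] = field(default_factory=lambda: {
        aa: gi for gi, grp in enumerate(_DEGENERATE_GROUPS) for aa in grp
    })

    @property
    def n_groups(self) -> int:
        return len(self.groups)


DEGENERATE = DegenerateAlphabet()


def map_degenerate(residue: str) -> int:
    """Group ordinal (0..8) of a canonical residue in the 9-group alphabet."""
    try:
        return DEGENERATE.index[residue]
    except KeyError:
        raise ValueError(
            f"residue {residue!r} is not one of the 20 canonical amino acids"
        ) from None


@dataclass(frozen=True)
class NkSpec:
    """A gapped (n,k)-mer feature specification.

    ``n`` is the maximal span in residues (3..10); ``k`` the tuple order
    (1..4).  For k <= 2 the plain 20-letter alphabet is used, for k > 2 the
    9-group degenerate alphabet.
    """

    n: int
    k: int

    def __post_init__(self) -> None:
        if not 3 <= self.n <= 10:
            raise ValueError(f"n must be in [3, 10], got {self.n}")
        if not 1 <= self.k <= 4:
            raise ValueError(f"k must be in [1, 4], got {self.k}")
        if self.k > self.n:
            raise ValueError(f"k ({self.k}) must not exceed n ({self.n})")

    @property
    def alphabet_size(self) -> int:
        return 20 if self.k <= 2 else 9

    @property
    def dimension(self) -> int:
        return self.alphabet_size ** self.k


@dataclass(frozen=True)
class FeatureConfig:
    """Which blocks make up the model input, and in what layout.

    The one-hot block (if enabled) comes first, position-major and
    residue-minor; then one count block per (n,k) spec, in list order, with
    tuples ordered lexicographically by symbol ordinal.  The default —
    one-hot over 100 positions plus (4,2) dimer counts — has dimension
    20*100 + 20^2 = 2400.
    """

    use_onehot: bool = True
    max_len: int = 100
    specs: tuple[NkSpec, ...] = (NkSpec(4, 2),)
    normalize_counts: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        if self.max_len < 1:
            raise ValueError("max_len must be positive")

    @property
    def onehot_dim(self) -> int:
        return 20 * self.max_len if self.use_onehot else 0

    @property
    def count_dim(self) -> int:
        return sum(s.dimension for s in self.specs)

    @property
    def dimension(self) -> int:
        return self.onehot_dim + self.count_dim


@dataclass(frozen=True)
class FeatureVector:
    """A dense feature vector with its generating configuration."""

    values: np.ndarray
    config: FeatureConfig

    def __post_init__(self) -> None:
        if self.values.shape != (self.config.dimension,):
            raise ValueError(
                f"feature length {self.values.shape} does not match config "
                f"dimension {self.config.dimension}"
            )


def _ordinals(peptide: str, degenerate: bool) -> np.ndarray:
    index = DEGENERATE.index if degenerate else AA_INDEX
    try:
        return np.array([index[aa] for aa in peptide], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"invalid residue {e.args[0]!r} in peptide") from None


def onehot_encode(peptide: str, max_len: int = 100) -> np.ndarray:
    """Padded one-hot coding: 20 entries per position, ``20*max_len`` total.

    Position i (0-based) occupies entries [20*i, 20*(i+1)) with a single 1
    at the residue's alphabetical ordinal; positions past the peptide's end
    stay all-zero (zero-padding to the maximal length).
    """
    if len(peptide) > max_len:
        raise ValueError(
            f"peptide length {len(peptide)} exceeds max_len {max_len}"
        )
    out = np.zeros(20 * max_len, dtype=np.float64)
    if peptide:
        ords = _ordinals(peptide, degenerate=False)
        out[20 * np.arange(len(ords)) + ords] = 1.0
    return out


def count_nk_mers(peptide: str, spec: NkSpec) -> np.ndarray:
    """Occurrence counts of every (n,k)-mer of ``spec`` in ``peptide``.

    Entry for symbol tuple t = number of position tuples
    ``i_1 < ... < i_k`` with span <= n whose (possibly degenerate-mapped)
    residues spell t.  Returns the zero vector when ``len(peptide) < k``.
    """
    a = spec.alphabet_size
    counts = np.zeros(spec.dimension, dtype=np.int64)
    if len(peptide) < spec.k:
        return counts
    s = _ordinals(peptide, degenerate=spec.k > 2)
    L = len(s)
    if spec.k == 1:
        np.add.at(counts, s, 1)
        return counts
    # enumerate gap patterns (g_1, ..., g_{k-1}), each >= 1, sum <= n-1,
    # then tally all windows of that pattern in one vectorized pass
    for gaps in _gap_patterns(spec.k - 1, spec.n - 1):
        total = sum(gaps)
        if L <= total:
            continue
        idx = s[: L - total].copy()
        off = 0
        for g in gaps:
            off += g
            idx = idx * a + s[off : L - total + off]
        np.add.at(counts, idx, 1)
    return counts


def _gap_patterns(m: int, max_sum: int):
    """All m-tuples of positive ints with sum <= max_sum."""
    for gaps in itertools.product(range(1, max_sum + 1), repeat=m):
        if sum(gaps) <= max_sum:
            yield gaps


def brute_force_oracle(peptide: str, spec: NkSpec) -> np.ndarray:
    """Reference count by explicit enumeration of every k-subset of positions.

    Deliberately shortcut-free: walks all C(L, k) index combinations,
    applies the span filter, and tallies symbol tuples.  Must agree exactly
    with :func:`count_nk_mers`.
    """
    a = spec.alphabet_size
    counts = np.zeros(spec.dimension, dtype=np.int64)
    if len(peptide) < spec.k:
        return counts
    s = _ordinals(peptide, degenerate=spec.k > 2)
    for combo in itertools.combinations(range(len(s)), spec.k):
        if combo[-1] - combo[0] + 1 > spec.n:
            continue
        flat = 0
        for i in combo:
            flat = flat * a + int(s[i])
        counts[flat] += 1
    return counts


def assemble_features(peptide: str, config: FeatureConfig | None = None) -> FeatureVector:
    """Concatenate the configured blocks for one peptide, in the fixed layout."""
    if config is None:
        config = FeatureConfig()
    blocks: list[np.ndarray] = []
    if config.use_onehot:
        blocks.append(onehot_encode(peptide, config.max_len))
    for spec in config.specs:
        counts = count_nk_mers(peptide, spec).astype(np.float64)
        if config.normalize_counts and len(peptide) > 0:
            counts /= len(peptide)
        blocks.append(counts)
    values = np.concatenate(blocks) if blocks else np.zeros(0)
    return FeatureVector(values=values, config=config)


def featurize_batch(
    peptides: list[str], config: FeatureConfig | None = None
) -> np.ndarray:
    """Feature matrix with one row per peptide (shape ``(N, dimension)``)."""
    if config is None:
        config = FeatureConfig()
    if not peptides:
        return np.zeros((0, config.dimension))
    return np.stack([assemble_features(p, config).values for p in peptides])
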