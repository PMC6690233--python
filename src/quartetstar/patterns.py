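"""Quartet site-pattern classification and the compact (n1..n5) representation.

With four aligned DNA sequences there are 4^4 = 256 possible site patterns
(columns). Under JC69 the likelihood of a column depends only on which OTUs
share which nucleotide, so the 256 raw patterns collapse into 15 equivalence
classes, grouped by the partition structure of the four OTUs:

    G1  all four nucleotides distinct          1 class,  multiplicity 24
    G2  exactly three distinct (one pair)      6 classes, multiplicity 24 each
    G3  two distinct, 3+1 split                4 classes, multiplicity 12 each
    G4  two distinct, 2+2 split (informative)  3 classes, multiplicity 12 each
    G5  monomorphic                            1 class,  multiplicity  4

A five-vector (n1, n2, n3, n4, n5) specifies an alignment with n1 G1 sites,
n2 copies of each of the six G2 classes, n3 of each G3 class, n4 of each G4
class and n5 G5 sites (total length n1 + 6 n2 + 4 n3 + 3 n4 + n5). Any such
alignment is exactly equidistant: all six pairwise Hamming distances equal
n1 + 5 n2 + 2 n3 + 2 n4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .jc69 import NUC_INDEX, NUCLEOTIDES

__all__ = [
    "PatternClass",
    "PatternCounts",
    "Alignment",
    "CLASSES",
    "GROUPS",
    "GROUP_SIZES",
    "MULTIPLICITIES",
    "REPRESENTATIVES",
    "classify_site",
    "enumerate_classes",
    "counts_from_spec",
    "counts_from_alignment",
    "alignment_from_spec",
    "symmetrize",
    "read_fasta",
    "write_fasta",
]

# OTU pairs indexing the six G2 classes (which pair shares the duplicated
# nucleotide) and, reused, the three G4 pairings 12|34, 13|24, 14|23.
_G2_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_G4_PAIRINGS = ("12|34", "13|24", "14|23")


@dataclass(frozen=True)
class PatternClass:
    """One of the 15 JC69 equivalence classes of quartet site patterns."""

    class_id: int  # 1..15, in canonical order (G1; 6x G2; 4x G3; 3x G4; G5)
    group: str  # "G1".."G5"
    representative: tuple[str, str, str, str]
    multiplicity: int  # raw patterns collapsed into this class
    label: str = ""  # human-readable detail (sharing pair / odd OTU / pairing)


def _build_classes() -> tuple[PatternClass, ...]:
    classes: list[PatternClass] = [
        PatternClass(1, "G1", ("A", "C", "G", "T"), 24, "all distinct")
    ]
    for k, (i, j) in enumerate(_G2_PAIRS):
        col = ["", "", "", ""]
        col[i] = col[j] = "A"
        rest = [o for o in range(4) if o not in (i, j)]
        col[rest[0]], col[rest[1]] = "C", "G"
        classes.append(
            PatternClass(2 + k, "G2", tuple(col), 24, f"S{i + 1}=S{j + 1}")
        )
    for odd in range(4):
        col = ["A"] * 4
        col[odd] = "C"
        classes.append(PatternClass(8 + odd, "G3", tuple(col), 12, f"S{odd + 1} odd"))
    for k, (i, j) in enumerate(_G2_PAIRS[:3]):  # pairs containing S1
        col = ["C"] * 4
        col[0] = col[j] = "A"
        classes.append(PatternClass(12 + k, "G4", tuple(col), 12, _G4_PAIRINGS[k]))
    classes.append(PatternClass(15, "G5", ("A", "A", "A", "A"), 4, "monomorphic"))
    return tuple(classes)


CLASSES: tuple[PatternClass, ...] = _build_classes()
GROUPS = ("G1", "G2", "G3", "G4", "G5")
GROUP_SIZES = {"G1": 1, "G2": 6, "G3": 4, "G4": 3, "G5": 1}
MULTIPLICITIES = np.array([c.multiplicity for c in CLASSES])
#: class representatives as integer codes, shape (15, 4)
REPRESENTATIVES = np.array(
    [[NUC_INDEX[b] for b in c.representative] for c in CLASSES]
)
# class ids (0-based) per group, in canonical order
GROUP_SLICES = {"G1": slice(0, 1), "G2": slice(1, 7), "G3": slice(7, 11),
                "G4": slice(11, 14), "G5": slice(14, 15)}


def enumerate_classes() -> list[PatternClass]:
    """The 15 pattern classes in canonical order (partition of all 256 columns)."""
    return list(CLASSES)


def classify_site(column) -> PatternClass:
    """Classify a 4-nucleotide column into its JC69 pattern class.

    The class is determined solely by which OTUs share nucleotides: within G2
    by the sharing pair, within G3 by the odd OTU, within G4 by the pairing.
    """
    if len(column) != 4:
        raise ValueError("a site column has exactly 4 nucleotides")
    try:
        codes = [NUC_INDEX[b] for b in column]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in column {column!r}") from None
    distinct = len(set(codes))
    if distinct == 4:
        return CLASSES[0]
    if distinct == 1:
        return CLASSES[14]
    if distinct == 3:
        dup = next(c for c in set(codes) if codes.count(c) == 2)
        pair = tuple(i for i in range(4) if codes[i] == dup)
        return CLASSES[1 + _G2_PAIRS.index(pair)]
    # two distinct nucleotides: 3+1 or 2+2 split
    c0 = codes.count(codes[0])
    if c0 == 1 or c0 == 3:
        minority = codes[0] if c0 == 1 else next(c for c in codes if codes.count(c) == 1)
        odd = codes.index(minority)
        return CLASSES[7 + odd]
    partner = next(i for i in range(1, 4) if codes[i] == codes[0])
    return CLASSES[11 + (partner - 1)]


@dataclass(frozen=True)
class PatternCounts:
    """Observed or specified counts over the 15 pattern classes."""

    counts: np.ndarray  # shape (15,), non-negative integers

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (15,):
            raise ValueError("counts must be a vector of 15 integers")
        if (arr < 0).any():
            raise ValueError("pattern counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def length(self) -> int:
        """Total number of sites."""
        return int(self.counts.sum())

    def group_totals(self) -> dict[str, int]:
        return {g: int(self.counts[GROUP_SLICES[g]].sum()) for g in GROUPS}

    def is_symmetric(self) -> bool:
        """True if counts are equal within each of G2, G3, G4."""
        return all(
            len(set(self.counts[GROUP_SLICES[g]].tolist())) == 1
            for g in ("G2", "G3", "G4")
        )

    def spec(self) -> tuple[int, int, int, int, int]:
        """The (n1..n5) vector, defined only for within-group-equal counts."""
        if not self.is_symmetric():
            raise ValueError("counts are not equal within groups; no (n1..n5) spec")
        c = self.counts
        return (int(c[0]), int(c[1]), int(c[7]), int(c[11]), int(c[14]))


def counts_from_spec(n1: int, n2: int, n3: int, n4: int, n5: int) -> PatternCounts:
    """Pattern counts for the equidistant spec (n1..n5).

    Each G2 class gets n2 sites, each G3 class n3, each G4 class n4; total
    length is n1 + 6 n2 + 4 n3 + 3 n4 + n5.
    """
    spec = (n1, n2, n3, n4, n5)
    if any(n < 0 for n in spec):
        raise ValueError(f"spec counts must be non-negative, got {spec}")
    if all(n == 0 for n in spec):
        raise ValueError("spec must contain at least one site")
    counts = np.array([n1] + [n2] * 6 + [n3] * 4 + [n4] * 3 + [n5])
    return PatternCounts(counts)


def symmetrize(counts: PatternCounts) -> PatternCounts:
    """Equalize counts within each of G2, G3 and G4 (group totals preserved).

    Mirrors post-processing that makes the six G2 patterns (and four G3,
    three G4) occur exactly equally, so the data support none of the three
    resolved topologies preferentially. Errors if a group total is not
    divisible by the group size, keeping dataset construction exact.
    """
    out = counts.counts.copy()
    for g in ("G2", "G3", "G4"):
        sl = GROUP_SLICES[g]
        total = int(out[sl].sum())
        size = GROUP_SIZES[g]
        if total % size:
            raise ValueError(
                f"{g} total {total} not divisible by {size}: cannot symmetrize exactly"
            )
        out[sl] = total // size
    return PatternCounts(out)


@dataclass(frozen=True)
class Alignment:
    """Four equal-length DNA sequences over the A/C/G/T alphabet."""

    names: tuple[str, str, str, str]
    sequences: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.names) != 4 or len(self.sequences) != 4:
            raise ValueError("quartet alignment requires exactly 4 sequences")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("sequences must have equal length")
        bad = set("".join(self.sequences)) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(
                f"non-nucleotide symbols {sorted(bad)} in alignment; "
                "remove or drop ambiguous columns first"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def columns(self):
        """Iterate over columns as 4-tuples of nucleotides."""
        return zip(*self.sequences)


def counts_from_alignment(aln: Alignment) -> PatternCounts:
    """Tally an alignment's columns over the 15 pattern classes."""
    counts = np.zeros(15, dtype=int)
    for col in aln.columns():
        counts[classify_site(col).class_id - 1] += 1
    return PatternCounts(counts)


def alignment_from_spec(n1: int, n2: int, n3: int, n4: int, n5: int,
                        names=("S1", "S2", "S3", "S4")) -> Alignment:
    """Deterministic canonical alignment realizing the spec (n1..n5).

    Concatenates each class's representative column, classes in canonical
    order, each repeated per its count. The result is equidistant: every
    pairwise Hamming distance equals n1 + 5 n2 + 2 n3 + 2 n4.
    """
    counts = counts_from_spec(n1, n2, n3, n4, n5).counts
    rows = [[], [], [], []]
    for cls, n in zip(CLASSES, counts):
        for otu in range(4):
            rows[otu].append(cls.representative[otu] * int(n))
    return Alignment(tuple(names), tuple("".join(r) for r in rows))


_AMBIGUOUS = set("RYSWKMBDHVN-.U")


def read_fasta(path, drop_ambiguous: bool = False) -> Alignment:
    """Read a 4-sequence nucleotide FASTA alignment.

    Ambiguity codes and gaps are a hard error unless ``drop_ambiguous`` is
    set, in which case columns containing any non-ACGT symbol are removed
    before counting (silent site dropping changes lnL, so it is opt-in).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 4:
        raise ValueError(f"expected 4 sequences, found {len(records)} in {path}")
    names = tuple(r.id for r in records)
    seqs = [str(r.seq).upper() for r in records]
    if drop_ambiguous:
        keep = [
            i for i in range(len(seqs[0]))
            if all(s[i] in NUCLEOTIDES for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    return Alignment(names, tuple(seqs))


def write_fasta(aln: Alignment, path) -> None:
    """Write a quartet alignment as plain FASTA."""
    records = [
        SeqRecord(Seq(s), id=n, description="")
        for n, s in zip(aln.names, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
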