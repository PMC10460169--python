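"""Strand-resolved small-RNA size distributions, 5' base bias, coverage and
RPKM abundance.

The size window is 15-35 nt.  Z-score profiles standardize the 42-cell
(size x strand) frequency vector jointly, which is what makes strongly
peaked contigs reach large positive values on a single cell while the
remaining cells sit slightly below zero.  RPKM is computed for 20-22 nt
reads only, with the library's total QC-passing read count as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq_io import AlignmentRecord, Contig, revcomp

__all__ = [
    "SIZE_MIN",
    "SIZE_MAX",
    "SIZES",
    "STRANDS",
    "SizeProfile",
    "ZProfile",
    "CoverageTrack",
    "Abundance",
    "size_profile",
    "zscore_profile",
    "coverage",
    "rpkm",
    "strand_ratio_21",
]

SIZE_MIN = 15
SIZE_MAX = 35
SIZES = tuple(range(SIZE_MIN, SIZE_MAX + 1))
STRANDS = ("+", "-")
_BASES = "ACGT"


@dataclass
class SizeProfile:
    """Read counts per size (15-35) and strand, with 5' base tallies."""

    contig_id: str = ""
    counts: np.ndarray = field(default_factory=lambda: np.zeros((len(SIZES), 2), dtype=int))
    five_prime: np.ndarray = field(
        default_factory=lambda: np.zeros((len(SIZES), 2, 4), dtype=int)
    )

    def count(self, size: int, strand: str) -> int:
        return int(self.counts[size - SIZE_MIN, STRANDS.index(strand)])

    def five_prime_count(self, size: int, strand: str, base: str) -> int:
        base = "T" if base == "U" else base
        return int(
            self.five_prime[size - SIZE_MIN, STRANDS.index(strand), _BASES.index(base)]
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def modal_size(self) -> Optional[int]:
        """Most frequent read size summed over strands (None if no reads)."""
        if self.total == 0:
            return None
        sums = self.counts.sum(axis=1)
        return SIZES[int(np.argmax(sums))]


@dataclass
class ZProfile:
    contig_id: str = ""
    z: np.ndarray = field(default_factory=lambda: np.zeros((len(SIZES), 2)))

    def value(self, size: int, strand: str) -> float:
        return float(self.z[size - SIZE_MIN, STRANDS.index(strand)])

    def flat(self) -> np.ndarray:
        return self.z.ravel()


@dataclass
class CoverageTrack:
    contig_id: str
    size_class: tuple[int, ...]
    plus: np.ndarray
    minus: np.ndarray

    @property
    def area(self) -> int:
        return int(self.plus.sum() + self.minus.sum())


@dataclass
class Abundance:
    contig_id: str
    library_id: str
    rpkm_20_22: float
    raw_count_20_22: int
    library_total: int


def size_profile(
    alignments: Iterable[AlignmentRecord],
    contig: Contig,
    reads_by_id: Optional[dict[str, str]] = None,
) -> SizeProfile:
    """Tally alignments on ``contig`` by read size and strand.

    The 5' base is that of the read as sequenced: for '-' strand records it
    is the complement of the contig base under the read's 5' end.  If
    ``reads_by_id`` maps read ids to sequences, the read's own first base
    is used instead (they differ only at mismatch positions).
    """
    prof = SizeProfile(contig_id=contig.id)
    for rec in alignments:
        if rec.contig_id != contig.id:
            raise ValueError(f"alignment of {rec.read_id} is not on contig {contig.id}")
        size = rec.read_length
        if size < SIZE_MIN or size > SIZE_MAX:
            continue
        si = size - SIZE_MIN
        ti = STRANDS.index(rec.strand)
        prof.counts[si, ti] += 1
        if reads_by_id is not None and rec.read_id in reads_by_id:
            base = reads_by_id[rec.read_id][0].upper().replace("U", "T")
        else:
            ref_base = contig.sequence[rec.five_prime]
            base = ref_base if rec.strand == "+" else revcomp(ref_base)
        if base in _BASES:
            prof.five_prime[si, ti, _BASES.index(base)] += 1
    return prof


def zscore_profile(profile: SizeProfile, per_strand: bool = False) -> ZProfile:
    """Z-standardize the size x strand frequency vector.

    By default the 42 cells are standardized jointly; ``per_strand=True``
    standardizes each strand's 21 cells separately.  Zero variance (all
    cells equal, including the all-zero profile) yields all-zero Z.
    """
    counts = profile.counts.astype(float)
    total = counts.sum()
    freq = counts / total if total > 0 else counts
    zp = ZProfile(contig_id=profile.contig_id)
    if per_strand:
        for ti in range(2):
            col = freq[:, ti]
            sd = col.std()
            zp.z[:, ti] = 0.0 if sd == 0 else (col - col.mean()) / sd
    else:
        sd = freq.std()
        zp.z = np.zeros_like(freq) if sd == 0 else (freq - freq.mean()) / sd
    return zp


def coverage(
    alignments: Iterable[AlignmentRecord],
    contig: Contig,
    size_class: Sequence[int] = (21,),
) -> CoverageTrack:
    """Per-position read depth on each strand for a size class.

    The summed area equals the total aligned nucleotides of the class
    (each alignment contributes its read length).
    """
    sizes = set(size_class)
    if not sizes <= set(SIZES):
        raise ValueError("size_class must be within 15..35")
    n = len(contig)
    plus = np.zeros(n, dtype=int)
    minus = np.zeros(n, dtype=int)
    for rec in alignments:
        if rec.read_length not in sizes:
            continue
        track = plus if rec.strand == "+" else minus
        track[rec.start : rec.end] += 1
    return CoverageTrack(contig_id=contig.id, size_class=tuple(sorted(sizes)), plus=plus, minus=minus)


def rpkm(
    alignments: Iterable[AlignmentRecord],
    contig: Contig,
    library_total: int,
    library_id: str = "",
    sizes: Sequence[int] = (20, 21, 22),
) -> Abundance:
    """Reads per kilobase of contig per million library reads, restricted
    to the given read sizes (default 20-22 nt)."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    size_set = set(sizes)
    raw = sum(1 for rec in alignments if rec.read_length in size_set)
    value = raw / ((len(contig) / 1000.0) * (library_total / 1e6))
    return Abundance(
        contig_id=contig.id,
        library_id=library_id,
        rpkm_20_22=value,
        raw_count_20_22=raw,
        library_total=library_total,
    )


def strand_ratio_21(profile: SizeProfile, size: int = 21) -> float:
    """Symmetry of the 21-nt peak: min/max of the two strand counts.

    1.0 for perfectly balanced strands, 0.0 when one strand is empty
    (including the degenerate both-empty case).
    """
    plus = profile.count(size, "+")
    minus = profile.count(size, "-")
    hi = max(plus, minus)
    if hi == 0:
        return 0.0
    return min(plus, minus) / hi


def profile_table(profile: SizeProfile) -> "np.ndarray":
    """Size x strand count matrix (21 x 2), convenience for TSV export."""
    return profile.counts.copy()
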