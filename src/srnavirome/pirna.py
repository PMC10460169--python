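"""Ping-pong piRNA signature detection and positional base bias.

Secondary piRNA biogenesis by the ping-pong cycle slices the target 10 nt
from the guide's 5' end, so sense/antisense 24-29 nt read pairs overlap by
exactly 10 nt between their 5' ends, with U enriched at position 1 of
antisense (responder) reads and A at position 10 of sense reads.  The
overlap-distance spectrum is standardized by Z-score; a signature is a
unique maximum at distance 10 exceeding the critical value.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seq_io import AlignmentRecord, Contig, revcomp

__all__ = ["PingPongResult", "BaseBiasMatrix", "pingpong", "base_bias"]

_BASES = "ACGT"


@dataclass
class PingPongResult:
    contig_id: str
    overlap_freq: np.ndarray  # index d-1 holds the count for distance d
    z: np.ndarray
    z10: float
    signature: bool
    n_sense: int = 0
    n_antisense: int = 0

    def freq(self, distance: int) -> int:
        return int(self.overlap_freq[distance - 1])

    def zscore(self, distance: int) -> float:
        return float(self.z[distance - 1])

    @property
    def peak_distance(self) -> Optional[int]:
        if self.overlap_freq.sum() == 0:
            return None
        return int(np.argmax(self.z)) + 1


@dataclass
class BaseBiasMatrix:
    strand: str
    freq: np.ndarray  # positions x 4 bases
    coverage: np.ndarray  # reads covering each position

    def frequency(self, position: int, base: str) -> float:
        base = "T" if base == "U" else base
        return float(self.freq[position - 1, _BASES.index(base)])


def _five_prime_counts(
    alignments: Iterable[AlignmentRecord], size_range: tuple[int, int]
) -> tuple[Counter, Counter]:
    lo, hi = size_range
    plus: Counter = Counter()
    minus: Counter = Counter()
    for rec in alignments:
        if not lo <= rec.read_length <= hi:
            continue
        if rec.strand == "+":
            plus[rec.five_prime] += 1
        else:
            minus[rec.five_prime] += 1
    return plus, minus


def pingpong(
    alignments: Sequence[AlignmentRecord],
    contig: Contig,
    size_range: tuple[int, int] = (24, 29),
    max_distance: int = 30,
    z_crit: float = 1.96,
) -> PingPongResult:
    """5'-5' overlap spectrum of opposite-strand read pairs.

    For a sense read with 5' end at p and an antisense read with 5' end at
    q >= p, the pair shares d = q - p + 1 five-prime-proximal nucleotides.
    All pairs are counted by 5'-position multiplicity.  Z is standardized
    over distances 1..``max_distance``; the signature flag requires the
    spectrum to peak at d = 10 with z10 >= ``z_crit``.
    """
    plus, minus = _five_prime_counts(alignments, size_range)
    hist = np.zeros(max_distance, dtype=np.int64)
    for p, np_count in plus.items():
        for d in range(1, max_distance + 1):
            q = p + d - 1
            if q in minus:
                hist[d - 1] += np_count * minus[q]
    n_sense = sum(plus.values())
    n_antisense = sum(minus.values())
    if n_sense == 0 or n_antisense == 0 or hist.sum() == 0:
        return PingPongResult(
            contig_id=contig.id,
            overlap_freq=hist,
            z=np.zeros(max_distance),
            z10=0.0,
            signature=False,
            n_sense=n_sense,
            n_antisense=n_antisense,
        )
    vals = hist.astype(float)
    sd = vals.std()
    z = np.zeros(max_distance) if sd == 0 else (vals - vals.mean()) / sd
    z10 = float(z[9]) if max_distance >= 10 else 0.0
    signature = max_distance >= 10 and int(np.argmax(z)) == 9 and z10 >= z_crit
    return PingPongResult(
        contig_id=contig.id,
        overlap_freq=hist,
        z=z,
        z10=z10,
        signature=signature,
        n_sense=n_sense,
        n_antisense=n_antisense,
    )


def base_bias(
    alignments: Sequence[AlignmentRecord],
    contig: Contig,
    size_range: tuple[int, int] = (24, 29),
    reads_by_id: Optional[dict[str, str]] = None,
) -> tuple[dict[str, BaseBiasMatrix], dict[str, float]]:
    """Per-position base frequencies of 24-29 nt reads, per strand.

    Frequencies are over the read as sequenced (5'->3' of the read
    itself); read sequences are reconstructed from the contig unless
    ``reads_by_id`` supplies them.  The summary reports U1 of antisense
    reads and A10 of sense reads, the two ping-pong hallmarks.
    """
    lo, hi = size_range
    max_pos = hi
    counts = {s: np.zeros((max_pos, 4), dtype=np.int64) for s in "+-"}
    cover = {s: np.zeros(max_pos, dtype=np.int64) for s in "+-"}
    for rec in alignments:
        if not lo <= rec.read_length <= hi:
            continue
        if reads_by_id is not None and rec.read_id in reads_by_id:
            seq = reads_by_id[rec.read_id].upper().replace("U", "T")
        else:
            seg = contig.sequence[rec.start : rec.end]
            seq = revcomp(seg) if rec.strand == "-" else seg
        mat = counts[rec.strand]
        cov = cover[rec.strand]
        for i, base in enumerate(seq[:max_pos]):
            cov[i] += 1
            if base in _BASES:
                mat[i, _BASES.index(base)] += 1
    matrices: dict[str, BaseBiasMatrix] = {}
    for s in "+-":
        if cover[s].sum() == 0:
            continue
        freq = np.zeros((max_pos, 4))
        nonzero = cover[s] > 0
        freq[nonzero] = counts[s][nonzero] / cover[s][nonzero, None]
        matrices[s] = BaseBiasMatrix(strand=s, freq=freq, coverage=cover[s])
    summary = {
        "U1_antisense": matrices["-"].frequency(1, "T") if "-" in matrices else float("nan"),
        "A10_sense": matrices["+"].frequency(10, "A") if "+" in matrices else float("nan"),
    }
    return matrices, summary
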