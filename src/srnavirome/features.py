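"""Genome-feature verification: ambigrammatic ORF layout, terminal G/C
runs, -1 frameshift slippery sites, capsid/RdRp frame layout, and
in-silico PCR.

Ambigrammatic narnaviruses carry a long ORF on the positive strand and an
overlapping long reverse ORF on the complement; their genomic termini show
complementary runs of G (5') and C (3').  Totiviruses translate the RdRp
by a -1 ribosomal frameshift at a slippery heptamer just upstream of the
capsid stop.  In-silico PCR reproduces expected amplicon sizes from primer
pairs without touching a thermocycler.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .curation import OrfCall
from .seq_io import Contig, revcomp

__all__ = [
    "AmbigramCall",
    "PrimerPair",
    "detect_ambigram",
    "check_terminal_runs",
    "find_slippery_sites",
    "detect_frameshift_layout",
    "insilico_pcr",
]


@dataclass
class AmbigramCall:
    seq_id: str
    forward_orf: Optional[OrfCall]
    reverse_orf: Optional[OrfCall]
    reciprocal_overlap: float
    is_ambigrammatic: bool


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str  # 5'->3'
    reverse: str  # 5'->3'
    expected_product: Optional[int] = None

    def __post_init__(self):
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"primer pair {self.name}: primers must be >= 15 nt")


def detect_ambigram(
    contig: Contig,
    orfs: Sequence[OrfCall],
    min_aa: int = 100,
    overlap_min: float = 0.5,
) -> AmbigramCall:
    """Compare the longest forward-strand ORF with the longest
    reverse-strand ORF on forward-strand coordinates.

    The call is ambigrammatic when both reach ``min_aa`` codons and their
    reciprocal overlap (shared span over each ORF's own span, taking the
    smaller fraction) reaches ``overlap_min``.
    """
    fwd = [o for o in orfs if o.frame > 0]
    rev = [o for o in orfs if o.frame < 0]
    f = max(fwd, key=lambda o: o.span) if fwd else None
    r = max(rev, key=lambda o: o.span) if rev else None
    if f is None or r is None:
        return AmbigramCall(contig.id, f, r, 0.0, False)
    overlap = max(0, min(f.end, r.end) - max(f.start, r.start))
    reciprocal = min(overlap / f.span, overlap / r.span) if overlap else 0.0
    is_amb = f.aa_length >= min_aa and r.aa_length >= min_aa and reciprocal >= overlap_min
    return AmbigramCall(contig.id, f, r, reciprocal, is_amb)


def _longest_run(segment: str, base: str) -> int:
    best = cur = 0
    for ch in segment:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def check_terminal_runs(
    sequence: str, min_run: int = 2, window: int = 12
) -> dict[str, object]:
    """Longest G run within the first ``window`` nt and C run within the
    last ``window`` nt of an oriented positive-strand sequence."""
    seq = sequence.upper()
    g_run = _longest_run(seq[:window], "G")
    c_run = _longest_run(seq[-window:], "C")
    return {
        "five_prime_G_run": g_run,
        "three_prime_C_run": c_run,
        "complementary": g_run >= min_run and c_run >= min_run,
    }


def find_slippery_sites(
    sequence: str,
    motifs: Iterable[str] = ("GGAAAAC",),
    use_consensus: bool = False,
    near: Optional[OrfCall] = None,
    margin: int = 30,
) -> list[int]:
    """0-based positions of -1 frameshift slippery heptamers.

    Default mode scans for the exact motifs; ``use_consensus=True`` adds
    every heptamer of the form XXXYYYZ (positions 1-3 identical and 4-6
    identical, Z free).  With ``near`` given, hits are restricted to the
    ``margin`` nt upstream of that ORF's stop codon.
    """
    seq = sequence.upper()
    positions: set[int] = set()
    for motif in motifs:
        m = motif.upper()
        start = 0
        while True:
            idx = seq.find(m, start)
            if idx == -1:
                break
            positions.add(idx)
            start = idx + 1
    if use_consensus:
        for i in range(len(seq) - 6):
            h = seq[i : i + 7]
            if h[0] == h[1] == h[2] and h[3] == h[4] == h[5]:
                positions.add(i)
    if near is not None:
        stop_pos = near.end - 3 if near.has_stop else near.end
        lo = max(0, stop_pos - margin)
        positions = {p for p in positions if lo <= p <= stop_pos}
    return sorted(positions)


def detect_frameshift_layout(
    orfs: Sequence[OrfCall], max_gap: int = 50
) -> list[tuple[OrfCall, OrfCall]]:
    """Candidate (capsid, polymerase) pairs translated via -1 frameshift.

    Pairs of same-strand ORFs where the downstream ORF lies one frame back
    (-1 mod 3) and starts inside, or within ``max_gap`` nt of, the 3' region
    of the upstream ORF.
    """
    pairs: list[tuple[OrfCall, OrfCall]] = []
    for a in orfs:
        for b in orfs:
            if a is b or a.strand != b.strand:
                continue
            if a.strand == "+":
                upstream, downstream = (a, b) if a.start <= b.start else (b, a)
                if downstream is not b:
                    continue
                gap_ok = b.start <= a.end + max_gap and b.end > a.end
            else:
                # on '-' the 3' direction runs towards lower forward coords
                if b.end > a.end:
                    continue
                gap_ok = b.end >= a.start - max_gap and b.start < a.start
            frame_a = a.start % 3 if a.strand == "+" else a.end % 3
            frame_b = b.start % 3 if b.strand == "+" else b.end % 3
            if (frame_b - frame_a) % 3 != 2:  # -1 shift
                continue
            if gap_ok:
                pairs.append((a, b))
    return pairs


def insilico_pcr(
    template: str, pair: PrimerPair, max_mismatch: int = 0
) -> list[int]:
    """Amplicon lengths for a primer pair on a template.

    The forward primer is matched on each strand and paired with every
    downstream site of the reverse complement of the reverse primer on
    the same strand; product length spans both primer 5' ends inclusive.
    """
    if not template:
        raise ValueError("empty template")
    seq = template.upper().replace("U", "T")
    fw = pair.forward.upper().replace("U", "T")
    rv_rc = revcomp(pair.reverse.upper().replace("U", "T"))

    def sites(hay: str, needle: str) -> list[int]:
        n = len(needle)
        out = []
        for i in range(len(hay) - n + 1):
            mm = sum(1 for a, b in zip(hay[i : i + n], needle) if a != b)
            if mm <= max_mismatch:
                out.append(i)
        return out

    products: list[int] = []
    for strand_seq in (seq, revcomp(seq)):
        fw_sites = sites(strand_seq, fw)
        rv_sites = sites(strand_seq, rv_rc)
        for f in fw_sites:
            for r in rv_sites:
                five_prime_rv = r + len(rv_rc) - 1
                if five_prime_rv > f:
                    length = five_prime_rv - f + 1
                    if length >= len(fw) + len(rv_rc):
                        products.append(length)
    return sorted(products)
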