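"""Desk-scale read-to-contig mapper with a bounded mismatch budget.

Reproduces the alignment contract of an ungapped short-read aligner run
with ``-v 1``: every reported placement is end-to-end, has at most
``max_mismatch`` mismatches, and belongs to the minimum-mismatch stratum
for that read.  Both strands are searched (the read's reverse complement
against the forward contig).  Sensitivity at one mismatch is guaranteed by
pigeonhole seeding: a read is split into two halves and any placement with
<= 1 mismatch matches at least one half exactly.  Reads too short to seed
fall back to a brute-force scan.

N bases in contigs never match any read base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seq_io import AlignmentRecord, Contig, SmallRead, revcomp

__all__ = ["MapperIndex", "build_index", "map_reads", "brute_force_map"]


@dataclass
class MapperIndex:
    """Exact k-mer seed table over the forward strand of every contig."""

    k: int
    seeds: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    contigs: dict[str, str] = field(default_factory=dict)


def build_index(contigs: Sequence[Contig], k: int = 10) -> MapperIndex:
    index = MapperIndex(k=k)
    for contig in contigs:
        seq = contig.sequence
        index.contigs[contig.id] = seq
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" in kmer:
                continue
            index.seeds.setdefault(kmer, []).append((contig.id, pos))
    return index


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count, with N in the reference never matching; > limit
    short-circuits to limit + 1."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or y == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _candidate_starts(read: str, index: MapperIndex) -> set[tuple[str, int]]:
    """Candidate (contig, start) positions from pigeonhole half-seeds."""
    k = index.k
    n = len(read)
    candidates: set[tuple[str, int]] = set()
    # left half-seed at read offset 0, right half-seed ending at the read end
    for offset in (0, n - k):
        kmer = read[offset : offset + k]
        for contig_id, pos in index.seeds.get(kmer, ()):
            start = pos - offset
            if start >= 0 and start + n <= len(index.contigs[contig_id]):
                candidates.add((contig_id, start))
    return candidates


def _scan_contig(read: str, contig_id: str, seq: str, max_mismatch: int):
    n = len(read)
    for start in range(len(seq) - n + 1):
        mm = _hamming(read, seq[start : start + n], max_mismatch)
        if mm <= max_mismatch:
            yield contig_id, start, mm


def map_reads(
    reads: Sequence[SmallRead],
    contigs: Sequence[Contig],
    max_mismatch: int = 1,
    index: MapperIndex | None = None,
    seed_k: int = 10,
) -> list[AlignmentRecord]:
    """Map reads to contigs on both strands, reporting all placements of
    the minimum-mismatch stratum with mismatches <= ``max_mismatch``.

    U residues in reads are normalized to T before matching.  Reads shorter
    than ``2 * seed_k`` (or any read when ``max_mismatch > 1``) are scanned
    brute-force so sensitivity never depends on seeding.
    """
    if index is None:
        index = build_index(contigs, k=seed_k)
    records: list[AlignmentRecord] = []
    for read in reads:
        fwd = read.sequence.upper().replace("U", "T")
        rev = revcomp(fwd)
        n = len(fwd)
        hits: list[tuple[str, int, str, int]] = []  # contig, start, strand, mm
        use_seed = max_mismatch <= 1 and n >= 2 * index.k
        for strand, oriented in (("+", fwd), ("-", rev)):
            if use_seed:
                for contig_id, start in _candidate_starts(oriented, index):
                    seq = index.contigs[contig_id]
                    mm = _hamming(oriented, seq[start : start + n], max_mismatch)
                    if mm <= max_mismatch:
                        hits.append((contig_id, start, strand, mm))
            else:
                for contig_id, seq in index.contigs.items():
                    for cid, start, mm in _scan_contig(oriented, contig_id, seq, max_mismatch):
                        hits.append((cid, start, strand, mm))
        if not hits:
            continue
        best = min(mm for *_ignored, mm in hits)
        for contig_id, start, strand, mm in sorted(set(hits)):
            if mm == best:
                records.append(
                    AlignmentRecord(
                        read_id=read.id,
                        contig_id=contig_id,
                        start=start,
                        strand=strand,
                        mismatches=mm,
                        read_length=n,
                    )
                )
    return records


def brute_force_map(
    reads: Sequence[SmallRead], contigs: Sequence[Contig], max_mismatch: int = 1
) -> list[AlignmentRecord]:
    """Exhaustive all-position, both-strand scan; the oracle the seeded
    mapper must agree with on small instances."""
    records: list[AlignmentRecord] = []
    for read in reads:
        fwd = read.sequence.upper().replace("U", "T")
        rev = revcomp(fwd)
        n = len(fwd)
        hits = []
        for strand, oriented in (("+", fwd), ("-", rev)):
            for contig in contigs:
                for cid, start, mm in _scan_contig(oriented, contig.id, contig.sequence, max_mismatch):
                    hits.append((cid, start, strand, mm))
        if not hits:
            continue
        best = min(mm for *_ignored, mm in hits)
        for cid, start, strand, mm in sorted(set(hits)):
            if mm == best:
                records.append(
                    AlignmentRecord(
                        read_id=read.id,
                        contig_id=cid,
                        start=start,
                        strand=strand,
                        mismatches=mm,
                        read_length=n,
                    )
                )
    return records
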