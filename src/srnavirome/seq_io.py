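"""Readers/writers for FASTA/FASTQ/SAM and annotation tables, plus small-RNA QC.

Small-RNA libraries arrive as Phred+33 FASTQ.  QC follows the standard
small-RNA preprocessing contract: optional 3' adapter trimming (and an
optional fixed 5' clip for libraries barcoded with extra inserted
nucleotides), then discarding of reads that are shorter than 15 nt, contain
ambiguous bases, or have a mean Phred quality below 20.  Contigs are
admitted at >= 200 nt.  Alignments are interchanged as SAM with the NM tag
carrying the mismatch count.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SmallRead",
    "Contig",
    "AlignmentRecord",
    "AnnotationRecord",
    "QCParams",
    "QCReport",
    "Category",
    "load_reads",
    "load_contigs",
    "import_alignments",
    "export_alignments",
    "classify_by_annotation",
    "load_annotations",
    "write_annotations",
]

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


class Category(str, Enum):
    VIRAL = "viral"
    NON_VIRAL = "non-viral"
    UNKNOWN = "unknown"
    UNCLASSIFIED = "unclassified"


@dataclass
class SmallRead:
    """A QC'd small-RNA read (15-35 nt, unambiguous bases)."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    library_id: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Contig:
    id: str
    sequence: str
    library_of_origin: str = ""
    category: Category = Category.UNCLASSIFIED
    conflict: bool = False  # significant viral and non-viral hits

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class AlignmentRecord:
    """Placement of a read on a contig.

    ``start`` is the 0-based leftmost position on the contig forward strand;
    for '-' strand records the read as sequenced is the reverse complement
    of the contig interval.
    """

    read_id: str
    contig_id: str
    start: int
    strand: str  # '+' or '-'
    mismatches: int
    read_length: int

    @property
    def end(self) -> int:
        return self.start + self.read_length

    @property
    def five_prime(self) -> int:
        """Contig coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AnnotationRecord:
    contig_id: str
    subject_id: str
    e_value: float
    search_type: str  # 'nt' or 'aa'
    subject_class: str  # 'viral' or 'non-viral'

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.contig_id}")
        if self.search_type not in ("nt", "aa"):
            raise ValueError(f"search_type must be nt/aa, got {self.search_type}")


@dataclass
class QCParams:
    min_len: int = 15
    max_len: int = 35
    min_mean_phred: float = 20.0
    adapter: str = ""
    five_prime_clip: int = 0
    adapter_min_overlap: int = 3
    adapter_min_identity: float = 0.9


@dataclass
class QCReport:
    total: int = 0
    kept: int = 0
    discarded_quality: int = 0
    discarded_length: int = 0
    discarded_ambiguity: int = 0
    trimmed: int = 0

    def conserved(self) -> bool:
        return (
            self.kept
            + self.discarded_quality
            + self.discarded_length
            + self.discarded_ambiguity
            == self.total
        )


class FastqFormatError(ValueError):
    pass


def _find_adapter(seq: str, adapter: str, min_overlap: int, min_identity: float) -> int:
    """Leftmost start of the 3' adapter in ``seq``, or len(seq) if absent.

    The adapter is located by the longest prefix of ``adapter`` matching a
    suffix-anchored window of the read at >= ``min_identity``, requiring at
    least ``min_overlap`` matched positions.
    """
    n = len(seq)
    best = n
    for pos in range(n - min_overlap + 1):
        overlap = min(len(adapter), n - pos)
        if overlap < min_overlap:
            break
        window = seq[pos : pos + overlap]
        matches = sum(a == b for a, b in zip(window, adapter))
        if matches / overlap >= min_identity:
            best = pos
            break
    return best


def load_reads(
    fastq_path: str,
    qc: QCParams | None = None,
    library_id: str = "",
    keep_qualities: bool = False,
) -> tuple[list[SmallRead], QCReport]:
    """Parse a Phred+33 FASTQ file and apply small-RNA QC.

    Returns the surviving reads (uppercase, U normalized to T) and a
    :class:`QCReport`; each discarded read is attributed to exactly one
    rule, checked in the order length, ambiguity, quality, so the report's
    tallies partition the input.
    """
    if qc is None:
        qc = QCParams()
    reads: list[SmallRead] = []
    report = QCReport()
    try:
        records = list(FastqGeneralIterator(fastq_path))
    except ValueError as exc:
        raise FastqFormatError(f"malformed FASTQ in {fastq_path}: {exc}") from exc
    for idx, (title, seq, qual) in enumerate(records):
        report.total += 1
        if len(seq) != len(qual):
            raise FastqFormatError(f"record {idx}: sequence/quality length mismatch")
        seq = seq.upper().replace("U", "T")
        phreds = [ord(c) - 33 for c in qual]
        if any(p < 0 or p > 93 for p in phreds):
            raise FastqFormatError(f"record {idx}: qualities not Phred+33")
        if qc.five_prime_clip:
            seq = seq[qc.five_prime_clip :]
            phreds = phreds[qc.five_prime_clip :]
        if qc.adapter:
            cut = _find_adapter(seq, qc.adapter, qc.adapter_min_overlap, qc.adapter_min_identity)
            if cut < len(seq):
                seq = seq[:cut]
                phreds = phreds[:cut]
                report.trimmed += 1
        if len(seq) < qc.min_len or len(seq) > qc.max_len:
            report.discarded_length += 1
            continue
        if any(b not in "ACGT" for b in seq):
            report.discarded_ambiguity += 1
            continue
        if not phreds or sum(phreds) / len(phreds) < qc.min_mean_phred:
            report.discarded_quality += 1
            continue
        report.kept += 1
        rid = title.split()[0]
        reads.append(
            SmallRead(
                id=rid,
                sequence=seq,
                qualities=phreds if keep_qualities else None,
                library_id=library_id,
            )
        )
    return reads, report


def load_contigs(
    fasta_path: str, min_len: int = 200, library_of_origin: str = ""
) -> tuple[list[Contig], int]:
    """Load contigs >= ``min_len`` nt; returns (contigs, n_rejected_short).

    Sequences are uppercased; duplicate ids raise; an empty FASTA yields an
    empty list.
    """
    from Bio import SeqIO

    contigs: list[Contig] = []
    seen: set[str] = set()
    rejected = 0
    for rec in SeqIO.parse(fasta_path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) < min_len:
            rejected += 1
            continue
        contigs.append(Contig(id=rec.id, sequence=seq, library_of_origin=library_of_origin))
    return contigs, rejected


def export_alignments(
    records: Sequence[AlignmentRecord],
    sam_path: str,
    contigs: Sequence[Contig],
    reads_by_id: Optional[dict[str, str]] = None,
) -> None:
    """Write alignment records as SAM (NM tag carries the mismatch count)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.id, "LN": len(c)} for c in contigs],
    }
    ref_ids = {c.id: i for i, c in enumerate(contigs)}
    seq_by_id = {c.id: c.sequence for c in contigs}
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.reference_id = ref_ids[rec.contig_id]
            a.reference_start = rec.start
            a.flag = 16 if rec.strand == "-" else 0
            a.mapping_quality = 255
            a.cigarstring = f"{rec.read_length}M"
            if reads_by_id and rec.read_id in reads_by_id:
                read_seq = reads_by_id[rec.read_id]  # as sequenced, 5'->3'
            else:
                seg = seq_by_id[rec.contig_id][rec.start : rec.end]
                read_seq = revcomp(seg) if rec.strand == "-" else seg
            # SAM stores SEQ on the reference forward strand
            a.query_sequence = revcomp(read_seq) if rec.strand == "-" else read_seq
            a.set_tag("NM", rec.mismatches)
            out.write(a)


def import_alignments(
    sam_path: str,
    contigs: Optional[Sequence[Contig]] = None,
    max_mismatch: Optional[int] = None,
) -> list[AlignmentRecord]:
    """Read AlignmentRecords from SAM.

    If ``contigs`` is given, reference names absent from the contig set
    raise.  If ``max_mismatch`` is given, records exceeding it raise.
    """
    known = {c.id for c in contigs} if contigs is not None else None
    records: list[AlignmentRecord] = []
    offenders: set[str] = set()
    with pysam.AlignmentFile(sam_path, "r") as sam:
        if known is not None:
            offenders = {name for name in sam.references if name not in known}
            if offenders:
                raise ValueError(
                    "SAM references absent from contig set: " + ", ".join(sorted(offenders))
                )
        for a in sam:
            if a.is_unmapped:
                continue
            nm = a.get_tag("NM") if a.has_tag("NM") else 0
            rec = AlignmentRecord(
                read_id=a.query_name,
                contig_id=a.reference_name,
                start=a.reference_start,
                strand="-" if a.is_reverse else "+",
                mismatches=int(nm),
                read_length=a.query_length or a.infer_query_length() or 0,
            )
            if max_mismatch is not None and rec.mismatches > max_mismatch:
                raise ValueError(
                    f"record {rec.read_id}: NM={rec.mismatches} exceeds max_mismatch={max_mismatch}"
                )
            records.append(rec)
    return records


def load_annotations(tsv_path: str) -> list[AnnotationRecord]:
    """Read the similarity-annotation TSV.

    Expected header: contig_id, subject_id, e_value, search_type,
    subject_class.
    """
    import csv

    out: list[AnnotationRecord] = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                AnnotationRecord(
                    contig_id=row["contig_id"],
                    subject_id=row["subject_id"],
                    e_value=float(row["e_value"]),
                    search_type=row["search_type"],
                    subject_class=row["subject_class"],
                )
            )
    return out


def write_annotations(annotations: Sequence[AnnotationRecord], tsv_path: str) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("contig_id\tsubject_id\te_value\tsearch_type\tsubject_class\n")
        for a in annotations:
            fh.write(
                f"{a.contig_id}\t{a.subject_id}\t{a.e_value:g}\t{a.search_type}\t{a.subject_class}\n"
            )


def classify_by_annotation(
    contigs: Sequence[Contig],
    annotations: Sequence[AnnotationRecord],
    nt_threshold: float = 1e-5,
    aa_threshold: float = 1e-3,
) -> list[Contig]:
    """Set each contig's category from its similarity hits.

    viral if any significant viral hit (e-value below the per-search-type
    threshold); non-viral if only significant non-viral hits; unknown
    otherwise.  A contig with significant hits of both classes is called
    viral with ``conflict=True`` so downstream curation re-examines it.
    Deterministic and independent of annotation order.
    """
    by_contig: dict[str, list[AnnotationRecord]] = {}
    for ann in annotations:
        by_contig.setdefault(ann.contig_id, []).append(ann)
    for contig in contigs:
        hits = by_contig.get(contig.id, [])
        sig_viral = False
        sig_nonviral = False
        for h in hits:
            thr = nt_threshold if h.search_type == "nt" else aa_threshold
            if h.e_value < thr:
                if h.subject_class == "viral":
                    sig_viral = True
                else:
                    sig_nonviral = True
        if sig_viral:
            contig.category = Category.VIRAL
            contig.conflict = sig_nonviral
        elif sig_nonviral:
            contig.category = Category.NON_VIRAL
        else:
            contig.category = Category.UNKNOWN
    return list(contigs)
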