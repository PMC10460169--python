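"""Exogenous-virus vs putative-EVE discrimination and redundancy removal.

Replicating exogenous RNA viruses leave a symmetric 21-nt siRNA peak on
both strands, because Dicer-2 cleaves the dsRNA replication intermediate;
endogenous viral elements (EVEs) are transcribed from one genomic strand
only and typically carry interrupted ORFs.  The curation rule is therefore
a conjunction: a contig is called a putative EVE when its longest ORF is
truncated AND it lacks a symmetric 21-nt peak.

Redundant contigs are collapsed with a CD-HIT-style greedy clustering:
length-descending incremental assignment requiring >= 90% global identity
and >= 90% coverage of the shorter sequence against the cluster
representative, testing both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .profiles import SizeProfile, strand_ratio_21
from .seq_io import AnnotationRecord, Contig, revcomp

__all__ = [
    "OrfCall",
    "CurationVerdict",
    "ContigCluster",
    "find_orfs",
    "classify_exogenous",
    "pairwise_global_identity",
    "cluster_redundant",
    "drop_spiked_viruses",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    contig_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    start: int  # 0-based half-open on the forward strand
    end: int
    has_start: bool
    has_stop: bool
    aa_length: int

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"


@dataclass
class CurationVerdict:
    contig_id: str
    verdict: str  # 'exogenous' or 'putative_EVE'
    sirna_peak: bool
    symmetry: float
    orf_truncated: bool
    evidence: str = ""


@dataclass
class ContigCluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity: dict[str, float] = field(default_factory=dict)
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _orfs_one_strand(seq: str, contig_id: str, strand: str, contig_len: int, min_aa: int):
    """Maximal stop-free runs in the three frames of one strand.

    ``seq`` is the strand as read 5'->3'; coordinates are mapped back to
    the forward strand for '-' calls.
    """
    n = len(seq)
    for off in range(3):
        frame = off + 1
        runs: list[tuple[int, int, bool]] = []
        run_start = off
        pos = off
        while pos + 3 <= n:
            if seq[pos : pos + 3] in _STOPS:
                runs.append((run_start, pos + 3, True))  # span includes the stop
                run_start = pos + 3
            pos += 3
        if pos - run_start >= 3:
            runs.append((run_start, pos, False))  # edge ORF, no stop seen
        for s, e, has_stop in runs:
            if e - s < 3:
                continue
            n_codons = (e - s) // 3
            aa_len = n_codons - (1 if has_stop else 0)
            if aa_len < min_aa:
                continue
            coding_end = e - 3 if has_stop else e
            has_start = any(
                seq[p : p + 3] == "ATG" for p in range(s, coding_end, 3)
            )
            if strand == "+":
                fstart, fend = s, e
                fframe = frame
            else:
                fstart, fend = contig_len - e, contig_len - s
                fframe = -frame
            yield (
                OrfCall(
                    contig_id=contig_id,
                    frame=fframe,
                    start=fstart,
                    end=fend,
                    has_start=has_start,
                    has_stop=has_stop,
                    aa_length=aa_len,
                )
            )


def find_orfs(contig: Contig, min_aa: int = 50) -> list[OrfCall]:
    """Scan all six frames for maximal stop-free runs of >= ``min_aa``
    codons.

    An ORF is a maximal run of sense codons ending at a stop (included in
    its span) or at the contig edge (``has_stop=False``); ``has_start`` is
    true when an in-frame ATG lies within the run.
    """
    seq = contig.sequence.upper()
    n = len(seq)
    orfs: list[OrfCall] = []
    orfs.extend(_orfs_one_strand(seq, contig.id, "+", n, min_aa))
    orfs.extend(_orfs_one_strand(revcomp(seq), contig.id, "-", n, min_aa))
    orfs.sort(key=lambda o: (-o.aa_length, o.frame, o.start))
    return orfs


def classify_exogenous(
    contig: Contig,
    profile: SizeProfile,
    orfs: Sequence[OrfCall],
    symmetry_min: float = 0.1,
    peak_sizes: Sequence[int] = (21,),
    min_orf_frac: float = 0.5,
) -> CurationVerdict:
    """Call a contig exogenous-virus or putative-EVE.

    putative_EVE iff the longest ORF is truncated (span < ``min_orf_frac``
    of the contig, or lacking both start and stop without reaching a contig
    edge) and there is no symmetric siRNA peak (modal size in
    ``peak_sizes`` with strand ratio >= ``symmetry_min``).  Contigs with no
    aligned reads are putative EVEs by absence of small-RNA support.
    """
    if profile.total == 0:
        return CurationVerdict(
            contig_id=contig.id,
            verdict="putative_EVE",
            sirna_peak=False,
            symmetry=0.0,
            orf_truncated=not orfs,
            evidence="no small RNA support",
        )
    modal = profile.modal_size()
    sirna_peak = modal in set(peak_sizes)
    symmetry = strand_ratio_21(profile)
    if orfs:
        longest = max(orfs, key=lambda o: o.span)
        edge_spanning = longest.start == 0 or longest.end == len(contig)
        orf_truncated = (longest.span / len(contig) < min_orf_frac) or (
            not longest.has_start and not longest.has_stop and not edge_spanning
        )
    else:
        orf_truncated = True
    is_eve = orf_truncated and not (sirna_peak and symmetry >= symmetry_min)
    evidence = (
        f"modal_size={modal}, symmetry={symmetry:.3f}, "
        f"orf_truncated={orf_truncated}"
    )
    return CurationVerdict(
        contig_id=contig.id,
        verdict="putative_EVE" if is_eve else "exogenous",
        sirna_peak=sirna_peak,
        symmetry=symmetry,
        orf_truncated=orf_truncated,
        evidence=evidence,
    )


def _aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "nt":
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -0.5
    elif alphabet == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -0.5
    else:
        raise ValueError("alphabet must be 'nt' or 'aa'")
    return aligner


def pairwise_global_identity(
    seq_a: str, seq_b: str, alphabet: str = "nt"
) -> dict[str, float]:
    """Needleman-Wunsch global alignment summary.

    Returns identity (identical columns over columns where both sequences
    place a residue), coverage of the shorter sequence (its residues in
    residue-to-residue columns over its length) and the full alignment
    length.  Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    aligner = _aligner(alphabet)
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    both = 0
    ident = 0
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    shorter = min(len(a), len(b))
    return {
        "identity": ident / both if both else 0.0,
        "coverage_of_shorter": both / shorter,
        "aligned_length": len(aligned_a),
    }


def cluster_redundant(
    contigs: Sequence[Contig], c: float = 0.90, aS: float = 0.90
) -> list[ContigCluster]:
    """CD-HIT-style greedy clustering.

    Contigs are sorted longest-first; each joins the first existing
    cluster whose representative it matches at identity >= ``c`` and
    coverage-of-shorter >= ``aS`` (forward or reverse-complement
    orientation), otherwise it founds a new cluster.  Ties in length break
    by contig id for order stability.
    """
    ordered = sorted(contigs, key=lambda x: (-len(x), x.id))
    clusters: list[ContigCluster] = []
    reps: dict[str, str] = {}
    for contig in ordered:
        placed = False
        for cluster in clusters:
            rep_seq = reps[cluster.representative_id]
            best = None
            for seq in (contig.sequence, revcomp(contig.sequence)):
                res = pairwise_global_identity(seq, rep_seq, "nt")
                if best is None or res["identity"] > best["identity"]:
                    best = res
            if best["identity"] >= c and best["coverage_of_shorter"] >= aS:
                cluster.member_ids.append(contig.id)
                cluster.identity[contig.id] = best["identity"]
                cluster.coverage[contig.id] = best["coverage_of_shorter"]
                placed = True
                break
        if not placed:
            cluster = ContigCluster(representative_id=contig.id, member_ids=[contig.id])
            cluster.identity[contig.id] = 1.0
            cluster.coverage[contig.id] = 1.0
            clusters.append(cluster)
            reps[contig.id] = contig.sequence
    return clusters


def drop_spiked_viruses(
    clusters: Sequence[ContigCluster],
    annotations: Sequence[AnnotationRecord],
    exclusion_taxa: Iterable[str],
) -> tuple[list[ContigCluster], int]:
    """Remove clusters whose representative's best similarity hit matches
    an excluded taxon (case-insensitive substring of the subject id).

    Used to strip experimentally introduced viruses before co-occurrence
    analysis.  Returns (retained clusters, number removed).
    """
    taxa = [t.lower() for t in exclusion_taxa]
    best_hit: dict[str, AnnotationRecord] = {}
    for ann in annotations:
        cur = best_hit.get(ann.contig_id)
        if cur is None or ann.e_value < cur.e_value:
            best_hit[ann.contig_id] = ann
    kept: list[ContigCluster] = []
    removed = 0
    for cluster in clusters:
        hit = best_hit.get(cluster.representative_id)
        subject = hit.subject_id.lower() if hit else ""
        if subject and any(t in subject for t in taxa):
            removed += 1
        else:
            kept.append(cluster)
    return kept, removed
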