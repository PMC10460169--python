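"""Ground-truthed synthetic viromes for exercising every pipeline stage.

The generator emits contigs, per-library small-RNA read sets, truth
alignments, and similarity annotations with the statistical structure the
analysis assumes in real mosquito libraries:

* replicating viruses produce symmetric 21-nt siRNA peaks from both
  strands (Dicer-2 products of the dsRNA replication intermediate);
* piRNA-producing viruses add 24-29 nt reads, a configurable fraction of
  the antisense ones placed at the 10-nt 5'-5' ping-pong overlap with a
  sampled sense partner, with U1 (antisense) and A10 (sense) biases;
* non-specific degradation contributes 18-35 nt (non-21) reads biased to
  the exposed strand;
* segments of one virus share a per-library abundance fingerprint up to
  lognormal noise, the signal co-occurrence clustering exploits;
* EVE decoys have interrupted ORFs and one-strand piRNA-sized reads only;
* background reads from a random host sequence stay unassigned.

All randomness flows from a single integer seed; outputs are byte-stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seq_io import AlignmentRecord, Contig, AnnotationRecord, SmallRead, revcomp

__all__ = [
    "ReadModel",
    "VirusSpec",
    "TruthTable",
    "SyntheticVirome",
    "simulate_virome",
    "make_eve_decoy",
    "make_ambigram",
    "default_specs",
    "write_virome",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
# codons that are stop-free on the forward frame and whose reverse
# complements are also not stops (for ambigrammatic sequences)
_REV_STOPS = {"TTA", "CTA", "TCA"}


@dataclass
class ReadModel:
    sirna_fraction: float = 0.6
    pirna_fraction: float = 0.2
    degradation_fraction: float = 0.2
    pingpong_fraction: float = 0.8  # of antisense piRNA reads
    u1_bias: float = 0.8
    a10_bias: float = 0.8
    pirna_sense_fraction: float = 0.5
    degradation_strand_bias: float = 0.9  # P(+ strand)

    def validate(self) -> None:
        total = self.sirna_fraction + self.pirna_fraction + self.degradation_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"read-model fractions sum to {total}, expected 1")


@dataclass
class VirusSpec:
    name: str
    segment_lengths: Sequence[int]
    fingerprint: Sequence[float]  # expected relative abundance per library
    sense: str = "+"
    read_model: ReadModel = field(default_factory=ReadModel)
    ambigrammatic: bool = False
    terminal_runs: bool = False
    reference_name: Optional[str] = None
    unannotated_segments: Sequence[int] = ()

    @property
    def n_segments(self) -> int:
        return len(self.segment_lengths)

    def validate(self, n_libraries: int) -> None:
        self.read_model.validate()
        if len(self.fingerprint) != n_libraries:
            raise ValueError(
                f"{self.name}: fingerprint length {len(self.fingerprint)} != {n_libraries} libraries"
            )


@dataclass
class TruthTable:
    contig_class: dict[str, dict] = field(default_factory=dict)  # id -> virus/segment/class
    read_source: dict[str, tuple[str, str]] = field(default_factory=dict)  # read -> (contig, strand)

    def virus_of(self, contig_id: str) -> Optional[str]:
        entry = self.contig_class.get(contig_id)
        return entry["virus"] if entry else None


@dataclass
class SyntheticVirome:
    contigs: list[Contig]
    reads_by_library: dict[str, list[SmallRead]]
    alignments: list[AlignmentRecord]
    annotations: list[AnnotationRecord]
    truth: TruthTable
    host_sequence: str = ""


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_orf_sequence(rng: np.random.Generator, length: int, utr_frac: float = 0.05) -> str:
    """Contig with a single long ORF (ATG ... stop) spanning ~90% of it."""
    utr5 = max(3, int(length * utr_frac))
    utr3 = max(3, int(length * utr_frac))
    orf_len = ((length - utr5 - utr3) // 3) * 3
    codons = ["ATG"]
    sense_codons = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
    n_codons = orf_len // 3 - 2
    codons += list(rng.choice(sense_codons, size=max(0, n_codons)))
    codons.append("TAA")
    body = "".join(codons)
    utr5_seq = _random_seq(rng, utr5)
    rest = length - utr5 - len(body)
    utr3_seq = _random_seq(rng, max(0, rest))
    seq = (utr5_seq + body + utr3_seq)[:length]
    if len(seq) < length:
        seq += _random_seq(rng, length - len(seq))
    return seq


def make_ambigram(length: int, seed: int) -> str:
    """Sequence stop-free in frame +1 and the overlapping reverse frame,
    with a 5' G run and a 3' C run.

    Codons are sampled from the 58 codons that are neither stops nor
    reverse complements of stops; the first codon is GGG and the last CCC,
    both of which satisfy the constraint, providing the terminal runs.
    """
    if length % 3 != 0:
        raise ValueError("length must be divisible by 3")
    rng = np.random.default_rng(seed)
    ok = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS and a + b + c not in _REV_STOPS
    ]
    n_codons = length // 3
    codons = ["GGG"] + list(rng.choice(ok, size=max(0, n_codons - 2))) + ["CCC"]
    return "".join(codons[:n_codons])


def make_eve_decoy(
    length: int, seed: int, n_reads: int = 500, library_id: str = "lib1", contig_id: str = "eve"
) -> tuple[Contig, list[SmallRead], list[AlignmentRecord]]:
    """EVE decoy contig plus its one-strand, piRNA-sized read set.

    The contig's longest ORF is forced below half the contig length by
    inserting in-frame stops; reads are 24-29 nt, '+' strand only, with no
    21-nt component.
    """
    if length < 300:
        raise ValueError("decoy length must be >= 300")
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, length)
    seq = _truncate_orfs(seq, rng, max_frac=0.4)
    contig = Contig(id=contig_id, sequence=seq)
    reads: list[SmallRead] = []
    alignments: list[AlignmentRecord] = []
    for i in range(n_reads):
        size = int(rng.integers(24, 30))
        start = int(rng.integers(0, length - size + 1))
        read_seq = seq[start : start + size]
        rid = f"{contig_id}_r{i}"
        reads.append(SmallRead(id=rid, sequence=read_seq, library_id=library_id))
        alignments.append(
            AlignmentRecord(
                read_id=rid,
                contig_id=contig_id,
                start=start,
                strand="+",
                mismatches=0,
                read_length=size,
            )
        )
    return contig, reads, alignments


def _truncate_orfs(seq: str, rng: np.random.Generator, max_frac: float = 0.4) -> str:
    """Insert in-frame stop codons until the longest ORF span in all six
    frames drops below ``max_frac`` of the sequence."""
    from .curation import find_orfs

    seq_list = list(seq)
    for _ in range(200):
        contig = Contig(id="tmp", sequence="".join(seq_list))
        orfs = find_orfs(contig, min_aa=1)
        if not orfs:
            break
        longest = max(orfs, key=lambda o: o.span)
        if longest.span / len(seq_list) < max_frac:
            break
        mid = (longest.start + longest.end) // 2
        if longest.frame > 0:
            off = longest.start % 3
            pos = mid - ((mid - off) % 3)
            seq_list[pos : pos + 3] = list("TAA")
        else:
            # stop on the reverse strand: place reverse complement of TAA
            off = longest.end % 3
            pos = mid - ((mid - off) % 3)
            seq_list[pos : pos + 3] = list("TTA")
    return "".join(seq_list)


def _mutate(seq: str, pos: int, base: str) -> str:
    if pos >= len(seq):
        return seq
    return seq[:pos] + base + seq[pos + 1 :]


def _force_prob(target_freq: float) -> float:
    """Probability of forcing a base so its final frequency over random
    background (0.25) equals ``target_freq``."""
    return max(0.0, (target_freq - 0.25) / 0.75)


def _emit_reads_for_contig(
    rng: np.random.Generator,
    contig: Contig,
    model: ReadModel,
    n_reads: int,
    library_id: str,
    prefix: str,
) -> tuple[list[SmallRead], list[AlignmentRecord]]:
    """Sample one contig's reads in one library under the read model."""
    seq = contig.sequence
    n = len(seq)
    reads: list[SmallRead] = []
    alignments: list[AlignmentRecord] = []
    kinds = rng.choice(
        ["sirna", "pirna", "deg"],
        size=n_reads,
        p=[model.sirna_fraction, model.pirna_fraction, model.degradation_fraction],
    )
    # sense piRNA 5' ends sampled first so antisense partners can pair
    sense_pirna_positions: list[int] = []
    counter = 0
    for kind in kinds:
        rid = f"{prefix}_r{counter}"
        counter += 1
        if kind == "sirna":
            size = 21
            start = int(rng.integers(0, n - size + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            seg = seq[start : start + size]
            read_seq = seg if strand == "+" else revcomp(seg)
            mm = 0
        elif kind == "pirna":
            size = int(rng.integers(24, 30))
            if rng.random() < model.pirna_sense_fraction:
                strand = "+"
                start = int(rng.integers(0, n - size + 1))
                sense_pirna_positions.append(start)
                read_seq = seq[start : start + size]
                mm = 0
                if rng.random() < _force_prob(model.a10_bias) and read_seq[9] != "A":
                    read_seq = _mutate(read_seq, 9, "A")
                    mm = 1
            else:
                strand = "-"
                paired = sense_pirna_positions and rng.random() < model.pingpong_fraction
                if paired:
                    p = sense_pirna_positions[int(rng.integers(0, len(sense_pirna_positions)))]
                    five_prime = p + 9  # 10-nt 5'-5' overlap
                    start = five_prime - size + 1
                    if start < 0 or five_prime >= n:
                        start = int(rng.integers(0, n - size + 1))
                else:
                    start = int(rng.integers(0, n - size + 1))
                read_seq = revcomp(seq[start : start + size])
                mm = 0
                if rng.random() < _force_prob(model.u1_bias) and read_seq[0] != "T":
                    read_seq = _mutate(read_seq, 0, "T")
                    mm = 1
        else:  # degradation
            size = 21
            while size == 21:
                size = int(rng.integers(18, 36))
            size = min(size, n)
            start = int(rng.integers(0, n - size + 1))
            strand = "+" if rng.random() < model.degradation_strand_bias else "-"
            seg = seq[start : start + size]
            read_seq = seg if strand == "+" else revcomp(seg)
            mm = 0
        reads.append(SmallRead(id=rid, sequence=read_seq, library_id=library_id))
        alignments.append(
            AlignmentRecord(
                read_id=rid,
                contig_id=contig.id,
                start=start,
                strand=strand,
                mismatches=mm,
                read_length=size,
            )
        )
    return reads, alignments


def default_specs(n_libraries: int = 4) -> list[VirusSpec]:
    """The default three-virus, four-library study condition.

    Three multi-segment RNA viruses with distinct per-library abundance
    fingerprints: a narnavirus-like bisegmented virus (ambigrammatic, with
    terminal G/C runs, second segment left unannotated as dark matter), a
    bunyavirus-like bisegmented virus with strong piRNA production, and a
    third bisegmented virus.  Fingerprints are separated enough that
    co-occurrence carries signal, as observed across field libraries.
    """
    if n_libraries != 4:
        raise ValueError("default specs are defined for 4 libraries")
    return [
        VirusSpec(
            name="NarnaV",
            segment_lengths=(2901, 1002),
            fingerprint=(220.0, 190.0, 6.0, 4.0),
            ambigrammatic=True,
            terminal_runs=True,
            reference_name="narnavirus_ref",
            unannotated_segments=(1,),
            read_model=ReadModel(
                sirna_fraction=0.5, pirna_fraction=0.2, degradation_fraction=0.3
            ),
        ),
        VirusSpec(
            name="BunyaV",
            segment_lengths=(2000, 1400),
            fingerprint=(5.0, 12.0, 240.0, 10.0),
            reference_name="bunyavirus_ref",
            read_model=ReadModel(
                sirna_fraction=0.4, pirna_fraction=0.4, degradation_fraction=0.2
            ),
        ),
        VirusSpec(
            name="TotiV",
            segment_lengths=(1800, 900),
            fingerprint=(8.0, 4.0, 12.0, 180.0),
            reference_name="totivirus_ref",
            read_model=ReadModel(
                sirna_fraction=0.6, pirna_fraction=0.1, degradation_fraction=0.3
            ),
        ),
    ]


def simulate_virome(
    specs: Sequence[VirusSpec],
    n_libraries: int = 4,
    depth: int = 20_000,
    seed: int = 0,
    abundance_sigma: float = 0.3,
    host_fraction: float = 0.1,
    host_length: int = 10_000,
    n_eve_decoys: int = 0,
) -> SyntheticVirome:
    """Simulate a multi-library virome with known truth.

    Expected read share of a contig in a library is proportional to its
    virus's fingerprint entry times segment length, perturbed by lognormal
    noise (sigma ``abundance_sigma``) independently per contig x library;
    realized counts are multinomial at ``depth`` reads per library.  A
    ``host_fraction`` of each library is drawn from a random host sequence
    and left without any contig of origin.
    """
    for spec in specs:
        spec.validate(n_libraries)
    rng = np.random.default_rng(seed)
    truth = TruthTable()
    contigs: list[Contig] = []
    annotations: list[AnnotationRecord] = []
    contig_specs: list[tuple[Contig, VirusSpec, int]] = []
    for spec in specs:
        for si, seg_len in enumerate(spec.segment_lengths):
            cid = f"{spec.name}_S{si + 1}"
            if spec.ambigrammatic:
                core = make_ambigram(seg_len - seg_len % 3, int(rng.integers(2**31)))
                seq = core + _random_seq(rng, seg_len % 3)
            else:
                seq = _random_orf_sequence(rng, seg_len)
            contig = Contig(id=cid, sequence=seq)
            contigs.append(contig)
            contig_specs.append((contig, spec, si))
            truth.contig_class[cid] = {
                "virus": spec.name,
                "segment": si,
                "class": "exogenous",
            }
            if spec.reference_name and si not in set(spec.unannotated_segments):
                annotations.append(
                    AnnotationRecord(
                        contig_id=cid,
                        subject_id=spec.reference_name,
                        e_value=1e-30,
                        search_type="aa",
                        subject_class="viral",
                    )
                )
    for ei in range(n_eve_decoys):
        decoy, _reads, _alns = make_eve_decoy(
            600, int(rng.integers(2**31)), n_reads=0, contig_id=f"EVE_{ei + 1}"
        )
        contigs.append(decoy)
        truth.contig_class[decoy.id] = {"virus": None, "segment": None, "class": "EVE"}
    host_seq = _random_seq(rng, host_length)
    reads_by_library: dict[str, list[SmallRead]] = {}
    alignments: list[AlignmentRecord] = []
    for li in range(n_libraries):
        lib = f"lib{li + 1}"
        lib_reads: list[SmallRead] = []
        weights = np.array(
            [
                spec.fingerprint[li]
                * (len(contig) / 1000.0)
                * rng.lognormal(mean=0.0, sigma=abundance_sigma)
                for contig, spec, _si in contig_specs
            ]
        )
        n_host = int(round(depth * host_fraction))
        n_viral = depth - n_host
        if weights.sum() == 0:
            counts = np.zeros(len(contig_specs), dtype=int)
        else:
            counts = rng.multinomial(n_viral, weights / weights.sum())
        for (contig, spec, si), count in zip(contig_specs, counts):
            reads, alns = _emit_reads_for_contig(
                rng,
                contig,
                spec.read_model,
                int(count),
                lib,
                prefix=f"{lib}_{contig.id}",
            )
            lib_reads.extend(reads)
            alignments.extend(alns)
            for rec in alns:
                truth.read_source[rec.read_id] = (contig.id, rec.strand)
        for hi in range(n_host):
            size = int(rng.integers(18, 31))
            start = int(rng.integers(0, host_length - size + 1))
            rid = f"{lib}_host_r{hi}"
            lib_reads.append(SmallRead(id=rid, sequence=host_seq[start : start + size], library_id=lib))
            truth.read_source[rid] = ("host", "+")
        reads_by_library[lib] = lib_reads
    return SyntheticVirome(
        contigs=contigs,
        reads_by_library=reads_by_library,
        alignments=alignments,
        annotations=annotations,
        truth=truth,
        host_sequence=host_seq,
    )


def write_virome(virome: SyntheticVirome, outdir: str) -> dict[str, str]:
    """Write FASTA / per-library FASTQ / truth SAM / annotation TSV.

    Byte-identical given the same virome object; reads get a uniform
    Phred 40 quality string.
    """
    from . import seq_io

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    fasta = os.path.join(outdir, "contigs.fasta")
    with open(fasta, "w") as fh:
        for contig in virome.contigs:
            fh.write(f">{contig.id}\n{contig.sequence}\n")
    paths["contigs"] = fasta
    reads_by_id: dict[str, str] = {}
    for lib, reads in sorted(virome.reads_by_library.items()):
        fq = os.path.join(outdir, f"{lib}.fastq")
        with open(fq, "w") as fh:
            for read in reads:
                fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")
                reads_by_id[read.id] = read.sequence
        paths[lib] = fq
    sam = os.path.join(outdir, "truth.sam")
    seq_io.export_alignments(virome.alignments, sam, virome.contigs, reads_by_id=reads_by_id)
    paths["alignments"] = sam
    tsv = os.path.join(outdir, "annotations.tsv")
    seq_io.write_annotations(virome.annotations, tsv)
    paths["annotations"] = tsv
    truth_tsv = os.path.join(outdir, "truth_contigs.tsv")
    with open(truth_tsv, "w") as fh:
        fh.write("contig_id\tvirus\tsegment\tclass\n")
        for cid, entry in virome.truth.contig_class.items():
            fh.write(f"{cid}\t{entry['virus']}\t{entry['segment']}\t{entry['class']}\n")
    paths["truth"] = truth_tsv
    return paths
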