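"""Multi-segment virus association by co-occurrence across libraries.

Segments of one virus rise and fall together across independent
libraries, so rows of a contig x library RPKM matrix (20-22 nt reads)
cluster by virus under hierarchical clustering with Euclidean distance
and average linkage.  Co-occurrence groups are then merged with
shared-closest-reference links; Z-profile concordance (cosine >= 0.7) is
recorded as supporting evidence only.  This is the procedure that links a
dark-matter segment to the virus whose other segments it travels with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .profiles import Abundance, SizeProfile, ZProfile
from .curation import OrfCall
from .seq_io import AlignmentRecord, AnnotationRecord, Contig, revcomp

__all__ = [
    "AbundanceMatrix",
    "Dendrogram",
    "SegmentGroup",
    "build_matrix",
    "cocluster",
    "orient_contig",
    "group_segments",
    "dendrogram_to_newick",
]


@dataclass
class AbundanceMatrix:
    """Contig x library RPKM (20-22 nt reads) as a DataFrame wrapper."""

    data: pd.DataFrame  # rows: contig ids, cols: library ids

    @property
    def contig_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]


@dataclass
class SegmentGroup:
    group_id: str
    member_ids: list[str]
    basis: dict[str, set[str]] = field(default_factory=dict)  # member -> evidence


def build_matrix(
    abundances: Iterable[Abundance],
    admitted_contigs: Optional[Sequence[str]] = None,
) -> AbundanceMatrix:
    """Assemble the contig x library RPKM matrix from per-library
    abundance records; missing cells are 0."""
    rows: dict[str, dict[str, float]] = {}
    libraries: list[str] = []
    for ab in abundances:
        rows.setdefault(ab.contig_id, {})[ab.library_id] = ab.rpkm_20_22
        if ab.library_id not in libraries:
            libraries.append(ab.library_id)
    if admitted_contigs is not None:
        rows = {cid: rows.get(cid, {}) for cid in admitted_contigs}
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=libraries).fillna(0.0)
    df = df.loc[sorted(df.index)]
    if (df.values < 0).any():
        raise ValueError("negative abundance")
    return AbundanceMatrix(data=df)


def admit_contigs(
    contigs: Sequence[Contig],
    verdicts: dict[str, str],
    min_viral_len: int = 200,
    min_unknown_len: int = 500,
) -> list[str]:
    """Row-admission rule for the co-occurrence matrix: curated viral
    contigs of any admitted length, plus unknown contigs > ``min_unknown_len``
    with an exogenous-like profile."""
    admitted = []
    for c in contigs:
        verdict = verdicts.get(c.id)
        if c.category.value == "viral" and len(c) >= min_viral_len and verdict == "exogenous":
            admitted.append(c.id)
        elif c.category.value == "unknown" and len(c) > min_unknown_len and verdict == "exogenous":
            admitted.append(c.id)
    return admitted


def cocluster(
    matrix: AbundanceMatrix,
    cut_height: Optional[float] = None,
    n_groups: Optional[int] = None,
    standardize: bool = False,
) -> tuple[Dendrogram, dict[str, int]]:
    """Hierarchical clustering of contigs on raw RPKM rows.

    Euclidean distance, average linkage; flat groups by cutting at
    ``cut_height`` (default: median merge height).  A single row yields a
    singleton group.  Deterministic given input order.
    """
    labels = matrix.contig_ids
    if len(labels) == 0:
        return Dendrogram(linkage=np.empty((0, 4)), labels=[]), {}
    if len(labels) == 1:
        return Dendrogram(linkage=np.empty((0, 4)), labels=labels), {labels[0]: 1}
    values = matrix.data.values.astype(float)
    if standardize:
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        values = (values - values.mean(axis=0)) / sd
    dists = pdist(values, metric="euclidean")
    link = hierarchy.linkage(dists, method="average")
    dend = Dendrogram(linkage=link, labels=labels)
    if n_groups is not None:
        assignment = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")
    else:
        if cut_height is None:
            cut_height = float(np.median(link[:, 2]))
        assignment = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    groups = {label: int(g) for label, g in zip(labels, assignment)}
    return dend, groups


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Newick serialization with branch lengths from merge heights."""
    if len(dend.labels) == 0:
        return ";"
    if len(dend.labels) == 1:
        return f"{dend.labels[0]};"
    tree = hierarchy.to_tree(dend.linkage)

    def walk(node) -> str:
        if node.is_leaf():
            return dend.labels[node.id]
        left = walk(node.left)
        right = walk(node.right)
        bl_left = node.dist - (0 if node.left.is_leaf() else node.left.dist)
        bl_right = node.dist - (0 if node.right.is_leaf() else node.right.dist)
        if node.left.is_leaf():
            bl_left = node.dist
        if node.right.is_leaf():
            bl_right = node.dist
        return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"

    return walk(tree) + ";"


@dataclass
class PolarityReport:
    contig_id: str
    flipped: bool
    rule: str  # 'read-majority', 'orf', or 'none'
    majority_fraction: float


def orient_contig(
    contig: Contig,
    profile: SizeProfile,
    orfs: Sequence[OrfCall],
    majority_min: float = 0.6,
) -> tuple[Contig, PolarityReport]:
    """Adjust contig polarity so the positive strand is the one most
    exposed to degradation-derived small RNAs.

    The non-siRNA sizes (18-20 and 22-35 nt) are strand-biased towards the
    more abundant (positive) viral strand, unlike the symmetric 21-nt
    siRNAs.  If that majority reaches ``majority_min`` it decides; below
    it, the strand of the longest ORF decides.  Idempotent.
    """
    from .profiles import SIZES, SIZE_MIN

    counts = profile.counts
    mask = np.array([s != 21 and s >= 18 for s in SIZES])
    plus = int(counts[mask, 0].sum())
    minus = int(counts[mask, 1].sum())
    total = plus + minus
    majority = max(plus, minus) / total if total else 0.0
    if total and majority >= majority_min:
        rule = "read-majority"
        flip = minus > plus
    elif orfs:
        rule = "orf"
        longest = max(orfs, key=lambda o: o.span)
        flip = longest.strand == "-"
    elif total:
        rule = "read-majority"
        flip = minus > plus
    else:
        return contig, PolarityReport(contig.id, False, "none", majority)
    if flip:
        oriented = Contig(
            id=contig.id,
            sequence=revcomp(contig.sequence),
            library_of_origin=contig.library_of_origin,
            category=contig.category,
            conflict=contig.conflict,
        )
    else:
        oriented = contig
    return oriented, PolarityReport(contig.id, flip, rule, majority)


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def group_segments(
    flat_groups: dict[str, int],
    annotations: Sequence[AnnotationRecord] = (),
    zprofiles: Optional[dict[str, ZProfile]] = None,
    composition: Optional[dict[str, tuple[float, float]]] = None,
    profile_cosine_min: float = 0.7,
    composition_radius: float = 0.1,
) -> list[SegmentGroup]:
    """Merge co-occurrence groups with shared-closest-reference links.

    Two contigs whose best annotation hit names the same subject are
    placed in one group even if they co-cluster apart (different segments
    of one virus hit different reference segments of the same virus when
    subject ids share the virus label).  Z-profile cosine similarity and
    (GC, CpG O/E) proximity are recorded as supporting — never sole —
    evidence on members already grouped.
    """
    contigs = sorted(flat_groups)
    parent = {c: c for c in contigs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    basis: dict[str, set[str]] = {c: set() for c in contigs}
    by_group: dict[int, list[str]] = {}
    for c, g in flat_groups.items():
        by_group.setdefault(g, []).append(c)
    for members in by_group.values():
        for c in members:
            basis[c].add("co-occurrence")
        for other in members[1:]:
            union(members[0], other)
    # shared-closest-reference links
    best: dict[str, AnnotationRecord] = {}
    for ann in annotations:
        if ann.contig_id not in flat_groups:
            continue
        cur = best.get(ann.contig_id)
        if cur is None or ann.e_value < cur.e_value:
            best[ann.contig_id] = ann
    by_subject: dict[str, list[str]] = {}
    for cid, ann in best.items():
        by_subject.setdefault(ann.subject_id, []).append(cid)
    for subject, members in by_subject.items():
        if len(members) < 2:
            continue
        for c in members:
            basis[c].add("shared-reference")
        for other in members[1:]:
            union(members[0], other)
    # supporting evidence inside realized groups
    roots: dict[str, list[str]] = {}
    for c in contigs:
        roots.setdefault(find(c), []).append(c)
    groups: list[SegmentGroup] = []
    for i, root in enumerate(sorted(roots), start=1):
        members = sorted(roots[root])
        for a in members:
            for b in members:
                if a >= b:
                    continue
                if zprofiles and a in zprofiles and b in zprofiles:
                    if _cosine(zprofiles[a].flat(), zprofiles[b].flat()) >= profile_cosine_min:
                        basis[a].add("profile-concordance")
                        basis[b].add("profile-concordance")
                if composition and a in composition and b in composition:
                    da = np.array(composition[a])
                    db = np.array(composition[b])
                    if np.linalg.norm(da - db) <= composition_radius:
                        basis[a].add("composition-concordance")
                        basis[b].add("composition-concordance")
        groups.append(
            SegmentGroup(
                group_id=f"group_{i}",
                member_ids=members,
                basis={m: basis[m] for m in members},
            )
        )
    return groups
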