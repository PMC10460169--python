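"""Co-occurrence clustering, contig orientation, and segment grouping."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import random_seq
from srnavirome import association
from srnavirome.association import (
    AbundanceMatrix,
    build_matrix,
    cocluster,
    dendrogram_to_newick,
    group_segments,
    orient_contig,
)
from srnavirome.curation import find_orfs
from srnavirome.profiles import Abundance, rpkm, size_profile, zscore_profile
from srnavirome.seq_io import AlignmentRecord, AnnotationRecord, Contig
from srnavirome.synthetic_data import default_specs, simulate_virome


def matrix_from(rows: dict[str, list[float]], libs=None) -> AbundanceMatrix:
    libs = libs or [f"lib{i+1}" for i in range(len(next(iter(rows.values()))))]
    abundances = [
        Abundance(cid, lib, val, 0, 1)
        for cid, vals in rows.items()
        for lib, val in zip(libs, vals)
    ]
    return build_matrix(abundances)


class TestBuildMatrix:
    def test_missing_cell_is_zero(self):
        abundances = [
            Abundance("c1", "lib1", 3.0, 3, 1000),
            Abundance("c2", "lib2", 5.0, 5, 1000),
        ]
        m = build_matrix(abundances)
        assert m.data.loc["c1", "lib2"] == 0.0
        assert m.data.loc["c2", "lib1"] == 0.0

    def test_admitted_subset(self):
        abundances = [Abundance(f"c{i}", "lib1", float(i), i, 100) for i in range(5)]
        m = build_matrix(abundances, admitted_contigs=["c1", "c3"])
        assert m.contig_ids == ["c1", "c3"]

    def test_shared_pattern_for_same_virus(self, default_virome):
        """Segments of one virus share the zero/nonzero library pattern."""
        v = default_virome
        by_lib_contig = {}
        for a in v.alignments:
            lib = a.read_id.split("_")[0]
            by_lib_contig.setdefault((lib, a.contig_id), []).append(a)
        abundances = []
        for lib, reads in v.reads_by_library.items():
            for c in v.contigs:
                abundances.append(
                    rpkm(by_lib_contig.get((lib, c.id), []), c, len(reads), library_id=lib)
                )
        m = build_matrix(abundances)
        for virus in ("NarnaV", "BunyaV", "TotiV"):
            rows = m.data.loc[[f"{virus}_S1", f"{virus}_S2"]].values
            cos = rows[0] @ rows[1] / (np.linalg.norm(rows[0]) * np.linalg.norm(rows[1]))
            assert cos >= 0.8  # segments share the library fingerprint


class TestCocluster:
    def test_identical_rows_merge_at_zero(self):
        m = matrix_from({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [9.0, 9.0, 9.0]})
        dend, groups = cocluster(m)
        assert dend.heights[0] == pytest.approx(0.0)
        assert groups["a"] == groups["b"]

    def test_hand_euclidean_merge_order(self):
        """Rows (0,0,0,8) and (0,0,0,7) are distance 1 apart and must
        merge before either joins (9,9,9,0)."""
        m = matrix_from({"r1": [0, 0, 0, 8], "r2": [9, 9, 9, 0], "r3": [0, 0, 0, 7]})
        dend, groups = cocluster(m)
        assert groups["r1"] == groups["r3"] != groups["r2"]
        assert dend.heights[0] == pytest.approx(1.0)

    def test_heights_monotone(self, rng):
        rows = {f"c{i}": list(rng.random(4) * 10) for i in range(12)}
        dend, _ = cocluster(matrix_from(rows))
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_row_permutation_invariance(self, rng):
        rows = {f"c{i}": list(rng.random(4) * 10) for i in range(8)}
        _, g1 = cocluster(matrix_from(rows))
        shuffled = dict(reversed(list(rows.items())))
        _, g2 = cocluster(matrix_from(shuffled))
        # same partition up to relabelling
        keys = sorted(rows)
        ari = adjusted_rand_score([g1[k] for k in keys], [g2[k] for k in keys])
        assert ari == pytest.approx(1.0)

    def test_single_row_singleton(self):
        m = matrix_from({"only": [1.0, 2.0]})
        _, groups = cocluster(m)
        assert groups == {"only": 1}

    def test_segment_recovery_over_seeds(self):
        """All segments of each synthetic virus land in one flat group in
        >= 90% of 20 seeds (lognormal abundance noise, sigma 0.3)."""
        perfect = 0
        for seed in range(20):
            v = simulate_virome(default_specs(), depth=3000, seed=seed)
            by = {}
            for a in v.alignments:
                lib = a.read_id.split("_")[0]
                by.setdefault((lib, a.contig_id), []).append(a)
            abundances = [
                rpkm(by.get((lib, c.id), []), c, len(reads), library_id=lib)
                for lib, reads in v.reads_by_library.items()
                for c in v.contigs
            ]
            m = build_matrix(abundances)
            _, groups = cocluster(m)
            truth = [v.truth.virus_of(cid) for cid in m.contig_ids]
            pred = [groups[cid] for cid in m.contig_ids]
            perfect += adjusted_rand_score(truth, pred) == pytest.approx(1.0)
        assert perfect / 20 >= 0.9

    def test_newick_export(self):
        m = matrix_from({"a": [0.0, 1.0], "b": [0.0, 1.2], "c": [5.0, 5.0]})
        dend, _ = cocluster(m)
        nwk = dendrogram_to_newick(dend)
        assert nwk.endswith(";") and "a" in nwk and "c" in nwk


class TestOrientContig:
    def _profile(self, contig, spec):
        recs = []
        for i, (size, strand, n) in enumerate(spec):
            recs.extend(
                AlignmentRecord(f"r{i}_{j}", contig.id, 0, strand, 0, size)
                for j in range(n)
            )
        return size_profile(recs, contig)

    def test_majority_flip(self, rng):
        contig = Contig(id="c", sequence=random_seq(rng, 300))
        prof = self._profile(contig, [(26, "-", 90), (26, "+", 10), (21, "+", 50), (21, "-", 50)])
        oriented, report = orient_contig(contig, prof, [])
        assert report.flipped and report.rule == "read-majority"
        from srnavirome.seq_io import revcomp

        assert oriented.sequence == revcomp(contig.sequence)

    def test_weak_majority_defers_to_orf(self, rng):
        from srnavirome.synthetic_data import _random_orf_sequence

        contig = Contig(id="c", sequence=_random_orf_sequence(rng, 300))
        orfs = find_orfs(contig, min_aa=20)
        # 55/45 split: below the 60% majority threshold
        prof = self._profile(contig, [(26, "-", 55), (26, "+", 45)])
        _, report = orient_contig(contig, prof, orfs)
        assert report.rule == "orf"
        assert not report.flipped  # longest ORF is on '+'

    def test_symmetric_reads_plus_orf_unchanged(self, rng):
        from srnavirome.synthetic_data import _random_orf_sequence

        contig = Contig(id="c", sequence=_random_orf_sequence(rng, 300))
        orfs = find_orfs(contig, min_aa=20)
        prof = self._profile(contig, [(26, "-", 50), (26, "+", 50)])
        oriented, report = orient_contig(contig, prof, orfs)
        assert not report.flipped
        assert oriented.sequence == contig.sequence

    def test_idempotent(self, rng):
        contig = Contig(id="c", sequence=random_seq(rng, 300))
        prof = self._profile(contig, [(27, "-", 95), (27, "+", 5)])
        once, _ = orient_contig(contig, prof, [])
        # after flipping, the same reads map to the other strand
        prof2 = self._profile(once, [(27, "+", 95), (27, "-", 5)])
        twice, report2 = orient_contig(once, prof2, [])
        assert twice.sequence == once.sequence
        assert not report2.flipped

    def test_no_evidence_flagged(self, rng):
        contig = Contig(id="c", sequence=random_seq(rng, 300))
        prof = self._profile(contig, [])
        oriented, report = orient_contig(contig, prof, [])
        assert report.rule == "none" and not report.flipped


class TestGroupSegments:
    def test_shared_reference_merges_across_clusters(self):
        flat = {"a": 1, "b": 2}
        anns = [
            AnnotationRecord("a", "bunyavirus_X", 1e-20, "aa", "viral"),
            AnnotationRecord("b", "bunyavirus_X", 1e-10, "aa", "viral"),
        ]
        groups = group_segments(flat, anns)
        assert len(groups) == 1
        assert groups[0].basis["a"] >= {"co-occurrence", "shared-reference"}

    def test_profile_concordance_is_supporting_only(self, rng):
        """Concordant Z-profiles alone never merge two flat clusters."""
        from srnavirome.profiles import SizeProfile

        flat = {"a": 1, "b": 2}
        prof = SizeProfile(contig_id="a")
        prof.counts[6, 0] = 100  # same shape for both
        z = zscore_profile(prof)
        groups = group_segments(flat, [], zprofiles={"a": z, "b": z})
        assert len(groups) == 2

    def test_singleton_keeps_basis(self):
        groups = group_segments({"solo": 1})
        assert len(groups) == 1
        assert groups[0].basis["solo"] == {"co-occurrence"}

    def test_concordance_recorded_within_group(self, rng):
        from srnavirome.profiles import SizeProfile

        flat = {"a": 1, "b": 1}
        prof = SizeProfile()
        prof.counts[6, 0] = 100
        z = zscore_profile(prof)
        comp = {"a": (0.5, 1.0), "b": (0.52, 0.98)}
        groups = group_segments(flat, [], zprofiles={"a": z, "b": z}, composition=comp)
        assert groups[0].basis["a"] >= {
            "co-occurrence",
            "profile-concordance",
            "composition-concordance",
        }
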