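"""ORF calling, the EVE-vs-exogenous rule, global identity and greedy
redundancy clustering."""

import numpy as np
import pytest

from conftest import random_seq
from srnavirome.curation import (
    classify_exogenous,
    cluster_redundant,
    drop_spiked_viruses,
    find_orfs,
    pairwise_global_identity,
)
from srnavirome.profiles import size_profile
from srnavirome.seq_io import AlignmentRecord, AnnotationRecord, Contig, revcomp
from srnavirome.synthetic_data import make_eve_decoy


class TestFindOrfs:
    def test_hand_translation(self):
        contig = Contig(id="t", sequence="ATGAAATAA")
        orfs = [o for o in find_orfs(contig, min_aa=1) if o.frame == 1]
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.start == 0 and orf.end == 9
        assert orf.aa_length == 2  # MK, stop excluded
        assert orf.has_start and orf.has_stop

    def test_edge_orf_without_stop(self):
        contig = Contig(id="t", sequence="ATGAAACCCGGGACA")
        orfs = [o for o in find_orfs(contig, min_aa=1) if o.frame == 1]
        assert len(orfs) == 1
        assert not orfs[0].has_stop
        assert orfs[0].aa_length == 5

    def test_span_divisible_by_three(self, rng):
        contig = Contig(id="t", sequence=random_seq(rng, 500))
        for orf in find_orfs(contig, min_aa=1):
            assert (orf.end - orf.start) % 3 == 0

    def test_reverse_strand_coordinates(self):
        # reverse complement of ATGAAATAA placed inside a longer sequence
        insert = revcomp("ATGAAATAA")
        seq = "CCCCCC" + insert + "GGGGGG"
        contig = Contig(id="t", sequence=seq)
        rev = [o for o in find_orfs(contig, min_aa=2) if o.frame < 0 and o.has_start and o.has_stop]
        # maximal run on the reverse strand: CCC CCC ATG AAA TAA, ending at
        # the stop whose forward-strand image is positions [6, 9)
        assert any(o.start == 6 and o.end == 21 and o.aa_length == 4 for o in rev)
        assert seq[6:9] == revcomp("TAA")

    def test_min_aa_filter(self, rng):
        contig = Contig(id="t", sequence=random_seq(rng, 600))
        all_orfs = find_orfs(contig, min_aa=1)
        big = find_orfs(contig, min_aa=30)
        assert all(o.aa_length >= 30 for o in big)
        assert len(big) <= len(all_orfs)


def _profile(contig, spec):
    recs = []
    i = 0
    for size, strand, n in spec:
        for _ in range(n):
            recs.append(AlignmentRecord(f"r{i}", contig.id, 0, strand, 0, size))
            i += 1
    return size_profile(recs, contig)


class TestClassifyExogenous:
    def intact_contig(self, rng):
        # single long ORF spanning most of the contig
        from srnavirome.synthetic_data import _random_orf_sequence

        return Contig(id="x", sequence=_random_orf_sequence(rng, 600))

    def test_symmetric_peak_full_orf_is_exogenous(self, rng):
        contig = self.intact_contig(rng)
        prof = _profile(contig, [(21, "+", 80), (21, "-", 100), (26, "+", 30)])
        orfs = find_orfs(contig, min_aa=20)
        v = classify_exogenous(contig, prof, orfs)
        assert v.verdict == "exogenous"
        assert v.sirna_peak and v.symmetry == pytest.approx(0.8)

    def test_truncated_orf_no_peak_is_eve(self, rng):
        seq = random_seq(rng, 900)
        from srnavirome.synthetic_data import _truncate_orfs

        contig = Contig(id="e", sequence=_truncate_orfs(seq, rng))
        prof = _profile(contig, [(27, "+", 100)])  # one strand, piRNA-sized
        orfs = find_orfs(contig, min_aa=20)
        v = classify_exogenous(contig, prof, orfs)
        assert v.verdict == "putative_EVE"
        assert v.orf_truncated and not v.sirna_peak

    def test_synthetic_decoy_is_eve(self):
        contig, _reads, alns = make_eve_decoy(600, seed=42, n_reads=400)
        prof = size_profile(alns, contig)
        orfs = find_orfs(contig, min_aa=20)
        v = classify_exogenous(contig, prof, orfs)
        assert v.verdict == "putative_EVE"

    def test_rule_conjunction(self, rng):
        """A truncated ORF with a symmetric 21-nt peak stays exogenous;
        the EVE call needs both conditions."""
        from srnavirome.synthetic_data import _truncate_orfs

        contig = Contig(id="e", sequence=_truncate_orfs(random_seq(rng, 900), rng))
        prof = _profile(contig, [(21, "+", 100), (21, "-", 90)])
        v = classify_exogenous(contig, prof, find_orfs(contig, min_aa=20))
        assert v.verdict == "exogenous"

    def test_no_reads_is_eve(self, rng):
        contig = self.intact_contig(rng)
        v = classify_exogenous(contig, _profile(contig, []), find_orfs(contig, min_aa=20))
        assert v.verdict == "putative_EVE"
        assert "no small RNA support" in v.evidence

    def test_parameter_recovery_labelled_contigs(self, rng):
        """Sensitivity and specificity >= 0.95 on 40 labelled synthetic
        contigs (20 replicating viruses, 20 EVE decoys)."""
        from srnavirome.synthetic_data import ReadModel, VirusSpec, simulate_virome

        tp = tn = 0
        specs = [
            VirusSpec(
                name=f"V{i}",
                segment_lengths=(900,),
                fingerprint=(50.0,),
                read_model=ReadModel(
                    sirna_fraction=0.6, pirna_fraction=0.2, degradation_fraction=0.2
                ),
            )
            for i in range(20)
        ]
        virome = simulate_virome(specs, n_libraries=1, depth=8000, seed=202609, host_fraction=0.0)
        by_contig = {c.id: [] for c in virome.contigs}
        for a in virome.alignments:
            by_contig[a.contig_id].append(a)
        for contig in virome.contigs:
            prof = size_profile(by_contig[contig.id], contig)
            v = classify_exogenous(contig, prof, find_orfs(contig, min_aa=20))
            tp += v.verdict == "exogenous"
        for i in range(20):
            contig, _r, alns = make_eve_decoy(600, seed=1000 + i, n_reads=300, contig_id=f"eve{i}")
            prof = size_profile(alns, contig)
            v = classify_exogenous(contig, prof, find_orfs(contig, min_aa=20))
            tn += v.verdict == "putative_EVE"
        assert tp / 20 >= 0.95  # sensitivity
        assert tn / 20 >= 0.95  # specificity


class TestPairwiseIdentity:
    def test_identical(self):
        res = pairwise_global_identity("ACGTACGT", "ACGTACGT")
        assert res["identity"] == 1.0 and res["coverage_of_shorter"] == 1.0

    def test_hand_alignment(self):
        res = pairwise_global_identity("ACGTACGT", "ACGTACGA")
        assert res["identity"] == pytest.approx(7 / 8)

    def test_orientation_matters(self, rng):
        s = random_seq(rng, 60)
        res = pairwise_global_identity(s, revcomp(s))
        assert res["identity"] < 1.0

    def test_symmetry(self, rng):
        a, b = random_seq(rng, 80), random_seq(rng, 70)
        r1 = pairwise_global_identity(a, b)
        r2 = pairwise_global_identity(b, a)
        assert r1["identity"] == pytest.approx(r2["identity"], abs=1e-12)
        assert r1["coverage_of_shorter"] == pytest.approx(r2["coverage_of_shorter"], abs=1e-12)

    def test_substring_full_coverage(self, rng):
        s = random_seq(rng, 200)
        sub = s[5:195]
        res = pairwise_global_identity(s, sub)
        assert res["identity"] == pytest.approx(1.0)
        assert res["coverage_of_shorter"] == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_global_identity("", "ACGT")

    def test_aa_mode(self):
        res = pairwise_global_identity("MKVLAT", "MKVLAT", alphabet="aa")
        assert res["identity"] == 1.0


class TestClusterRedundant:
    def test_identical_pair_one_cluster(self, rng):
        s = random_seq(rng, 300)
        contigs = [Contig(id="a", sequence=s), Contig(id="b", sequence=s)]
        clusters = cluster_redundant(contigs)
        assert len(clusters) == 1 and clusters[0].size == 2

    def test_dissimilar_stay_apart(self, rng):
        contigs = [
            Contig(id="a", sequence=random_seq(rng, 300)),
            Contig(id="b", sequence=random_seq(rng, 300)),
        ]
        assert len(cluster_redundant(contigs)) == 2

    def test_substring_joins(self, rng):
        s = random_seq(rng, 400)
        contigs = [Contig(id="long", sequence=s), Contig(id="short", sequence=s[10:390])]
        clusters = cluster_redundant(contigs)
        assert len(clusters) == 1
        assert clusters[0].representative_id == "long"

    def test_revcomp_orientation_joins(self, rng):
        s = random_seq(rng, 300)
        contigs = [Contig(id="fwd", sequence=s), Contig(id="rev", sequence=revcomp(s))]
        assert len(cluster_redundant(contigs)) == 1

    def test_thresholds_hold_post_hoc(self, rng):
        s = random_seq(rng, 300)
        variants = []
        for i in range(4):
            v = list(s)
            for p in rng.integers(0, 300, size=i * 12):
                v[p] = "A" if v[p] != "A" else "C"
            variants.append(Contig(id=f"v{i}", sequence="".join(v)))
        clusters = cluster_redundant(variants)
        reps = {c.representative_id: c for c in clusters}
        for cl in clusters:
            for m in cl.member_ids:
                assert cl.identity[m] >= 0.90
                assert cl.coverage[m] >= 0.90


class TestDropSpiked:
    def make_clusters(self, n, rng):
        return [
            type(cluster_redundant([Contig(id=f"c{i}", sequence=random_seq(rng, 250))])[0])(
                representative_id=f"c{i}", member_ids=[f"c{i}"]
            )
            for i in range(n)
        ]

    def test_exclusion_arithmetic(self, rng):
        """56 clusters minus 17 spiked-virus matches leaves 39."""
        clusters = self.make_clusters(56, rng)
        anns = []
        for i in range(3):
            anns.append(AnnotationRecord(f"c{i}", "Usutu virus strain X", 1e-20, "nt", "viral"))
        for i in range(3, 17):
            anns.append(AnnotationRecord(f"c{i}", "Zika virus isolate Y", 1e-30, "nt", "viral"))
        kept, removed = drop_spiked_viruses(clusters, anns, ["Usutu", "Zika"])
        assert removed == 17
        assert len(kept) == 39

    def test_empty_exclusion_is_identity(self, rng):
        clusters = self.make_clusters(5, rng)
        kept, removed = drop_spiked_viruses(clusters, [], [])
        assert len(kept) == 5 and removed == 0

    def test_all_excluded(self, rng):
        clusters = self.make_clusters(3, rng)
        anns = [AnnotationRecord(f"c{i}", "Zika virus", 1e-9, "nt", "viral") for i in range(3)]
        kept, removed = drop_spiked_viruses(clusters, anns, ["zika"])
        assert kept == [] and removed == 3
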