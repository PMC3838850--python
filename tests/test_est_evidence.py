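import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genechain.est_evidence import (
    ClusterConfig,
    EstCluster,
    assemble_est_transcripts,
    cluster_alignments,
    extract_cds,
    filter_alignments,
    infer_introns,
    longest_orf,
    mod3_profile,
)
from genechain.formats_io import GenomeSequence, SplicedAlignment


def aln(est_id, blocks, strand="+", identity=1.0, coverage=1.0, seqid="chr"):
    return SplicedAlignment(est_id=est_id, seqid=seqid, strand=strand,
                            blocks=blocks, identity=identity,
                            coverage=coverage)


class TestFilter:
    CFG = ClusterConfig()

    @pytest.mark.parametrize(
        "identity,coverage,kept",
        [
            (0.94, 0.95, False),   # identity below 95%
            (0.95, 0.95, True),    # identity exactly at the threshold
            (0.99, 0.91, True),    # coverage above 90%
            (0.99, 0.90, False),   # coverage exactly 90%: "greater than"
            (0.99, 0.8999, False),
        ],
    )
    def test_threshold_semantics(self, identity, coverage, kept):
        a = aln("e", [(1, 100)], identity=identity, coverage=coverage)
        got_kept, got_disc = filter_alignments([a], self.CFG)
        assert (a in got_kept) is kept

    def test_human_style_identity_preset(self):
        cfg = ClusterConfig(min_identity=0.98)
        a = aln("e", [(1, 100)], identity=0.97, coverage=0.95)
        kept, _ = filter_alignments([a], cfg)
        assert kept == []

    def test_filter_idempotent(self):
        alns = [aln(f"e{i}", [(1, 100)], identity=0.9 + 0.02 * i,
                    coverage=0.95) for i in range(5)]
        kept1, _ = filter_alignments(alns, self.CFG)
        kept2, _ = filter_alignments(kept1, self.CFG)
        assert kept1 == kept2


class TestClustering:
    CFG = ClusterConfig()

    def test_shared_splice_site_links(self):
        a = aln("A", [(101, 200), (301, 400)])
        b = aln("B", [(150, 200), (301, 380), (501, 600)])
        clusters = cluster_alignments([a, b], self.CFG)
        assert len(clusters) == 1
        assert {m.est_id for m in clusters[0].members} == {"A", "B"}

    def test_disjoint_alignments_split(self):
        a = aln("A", [(101, 200), (301, 400)])
        c = aln("C", [(501, 600), (701, 800)])
        clusters = cluster_alignments([a, c], self.CFG)
        assert len(clusters) == 2

    def test_unspliced_attaches_same_strand_only(self):
        a = aln("A", [(101, 200), (301, 400)])
        b = aln("B", [(105, 200), (301, 420)])
        u_same = aln("U1", [(150, 260)])
        u_opp = aln("U2", [(150, 260)], strand="-")
        clusters = cluster_alignments([a, b, u_same, u_opp], self.CFG)
        by_members = {frozenset(m.est_id for m in c.members) for c in clusters}
        assert frozenset({"A", "B", "U1"}) in by_members
        assert frozenset({"U2"}) in by_members

    def test_order_invariance(self):
        items = [
            aln("A", [(101, 200), (301, 400)]),
            aln("B", [(150, 200), (301, 380)]),
            aln("C", [(501, 600), (701, 800)]),
            aln("U", [(120, 180)]),
        ]
        ref = cluster_alignments(items, self.CFG)
        perm = cluster_alignments(items[::-1], self.CFG)
        key = lambda cs: sorted(
            frozenset(m.est_id for m in c.members) for c in cs
        )
        assert key(ref) == key(perm)

    def test_boundary_tolerance_links_near_sites(self):
        a = aln("A", [(101, 200), (301, 400)])
        b = aln("B", [(101, 202), (303, 400)])  # both sites shifted by 2
        linked = cluster_alignments([a, b], ClusterConfig(boundary_tolerance=3))
        split = cluster_alignments([a, b], ClusterConfig(boundary_tolerance=1))
        assert len(linked) == 1 and len(split) == 2


def genome_with_intron(intron=(201, 300), L=600, strand="+"):
    rng = np.random.default_rng(4)
    seq = list("".join(rng.choice(list("ACGT"), size=L)))
    s, e = intron
    if strand == "+":
        seq[s - 1 : s + 1] = "GT"
        seq[e - 2 : e] = "AG"
    else:
        seq[s - 1 : s + 1] = "CT"
        seq[e - 2 : e] = "AC"
    return GenomeSequence("chr", "".join(seq))


class TestInferIntrons:
    CFG = ClusterConfig()

    def cluster(self, members, strand="+"):
        return EstCluster("cluster_0001", "chr", strand, members)

    def test_consensus_support(self):
        g = genome_with_intron((201, 300))
        cl = self.cluster([aln("A", [(101, 200), (301, 400)]),
                           aln("B", [(120, 200), (301, 380)])])
        introns = infer_introns(cl, g, self.CFG)
        assert len(introns) == 1
        it = introns[0]
        assert (it.start, it.end, it.support) == (201, 300, 2)

    def test_shift_to_canonical_site(self):
        g = genome_with_intron((201, 300))
        # one gap misplaced by 2; merged group canonicalizes at (201,300)
        cl = self.cluster([aln("A", [(101, 200), (301, 400)]),
                           aln("B", [(101, 202), (303, 400)])])
        introns = infer_introns(cl, g, self.CFG)
        assert [(i.start, i.end) for i in introns] == [(201, 300)]
        assert introns[0].support == 2

    def test_noncanonical_gap_dropped(self):
        rng = np.random.default_rng(8)
        # genome of C/A only: no GT anywhere
        g = GenomeSequence("chr", "".join(rng.choice(list("CA"), size=600)))
        cl = self.cluster([aln("A", [(101, 200), (301, 400)])])
        assert infer_introns(cl, g, self.CFG) == []

    def test_minus_strand_canonical(self):
        g = genome_with_intron((201, 300), strand="-")
        cl = self.cluster([aln("A", [(101, 200), (301, 400)], strand="-")],
                          strand="-")
        introns = infer_introns(cl, g, self.CFG)
        assert [(i.start, i.end, i.strand) for i in introns] == \
            [(201, 300, "-")]

    def test_zero_error_full_recovery(self, sim_world):
        """With exact alignments every inferred intron equals a true one."""
        from genechain.est_evidence import filter_alignments as fa
        genome = sim_world["genome"]
        params = sim_world["params"]
        kept, _ = fa(sim_world["alignments"], self.CFG)
        clusters = cluster_alignments(kept, self.CFG)
        inferred = set()
        for cl in clusters:
            for it in infer_introns(cl, genome, self.CFG, pwms=params.pwms):
                inferred.add((it.strand, it.start, it.end))
        truth = {(t.strand, s, e) for t in sim_world["truth_tx"]
                 for (s, e) in t.introns}
        assert inferred == truth


class TestEstTranscripts:
    CFG = ClusterConfig()

    def run(self, members, genome=None, strand="+"):
        g = genome or genome_with_intron((201, 300), strand=strand)
        cl = EstCluster("cluster_0001", "chr", strand, members)
        introns = infer_introns(cl, g, self.CFG)
        return assemble_est_transcripts(cl, introns)

    def test_identical_chains_merge_to_union(self):
        ts = self.run([aln("A", [(101, 200), (301, 400)]),
                       aln("B", [(150, 200), (301, 450)])])
        assert len(ts) == 1
        assert ts[0].exons == [(101, 200), (301, 450)]
        assert ts[0].supporting_est_ids == ["A", "B"]

    def test_conflicting_intron_boundaries_stay_separate(self):
        g = genome_with_intron((201, 300))
        # second intron boundary conflict: B's intron overlaps A's exon
        s2, e2 = 321, 380
        seq = list(g.seq)
        seq[s2 - 1 : s2 + 1] = "GT"
        seq[e2 - 2 : e2] = "AG"
        g = GenomeSequence("chr", "".join(seq))
        ts = self.run(
            [aln("A", [(101, 200), (301, 400)]),
             aln("B", [(101, 200), (301, 320), (381, 450)])],
            genome=g,
        )
        assert len(ts) == 2

    def test_no_two_outputs_mergeable(self):
        g = genome_with_intron((201, 300))
        for extra in [(321, 380), (331, 390)]:
            seq = list(g.seq)
            seq[extra[0] - 1 : extra[0] + 1] = "GT"
            seq[extra[1] - 2 : extra[1]] = "AG"
            g = GenomeSequence("chr", "".join(seq))
        members = [
            aln("A", [(101, 200), (301, 400)]),
            aln("B", [(101, 200), (301, 320), (381, 450)]),
            aln("C", [(110, 200), (301, 330), (391, 440)]),
        ]
        ts = self.run(members, genome=g)
        # pairwise non-mergeable: conflicting introns in every overlap
        from genechain.est_evidence import _structures_compatible
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                assert not _structures_compatible(ts[i].exons, ts[j].exons)


class TestLongestOrf:
    def test_printed_example(self):
        assert longest_orf("AAATGAAACCCTAGAA") == (3, 14, 2)

    def test_no_atg_returns_none(self):
        assert longest_orf("CCCCCCTAGCCC") is None

    def test_tie_breaks_to_five_prime(self):
        # two ORFs of equal length in different frames
        seq = "ATGAAATAG" + "C" + "ATGCCCTGA"
        got = longest_orf(seq)
        assert got == (1, 9, 0)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(40):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            got = longest_orf(seq)
            best = None
            for f in range(3):
                for i in range(f, len(seq) - 2, 3):
                    if seq[i : i + 3] != "ATG":
                        continue
                    for j in range(i + 3, len(seq) - 2, 3):
                        cod = seq[j : j + 3]
                        if cod in ("TAA", "TAG", "TGA"):
                            cand = (j + 3 - i, -(i + 1))
                            if best is None or cand > best[0]:
                                best = (cand, (i + 1, j + 3, i % 3))
                            break
            assert got == (best[1] if best else None)


class TestExtractCds:
    def test_orf_maps_back_across_intron(self, sim_world):
        genome = sim_world["genome"]
        t = sim_world["truth_tx"][0]
        from genechain.est_evidence import EstTranscript
        est = EstTranscript("e.t1", t.seqid, t.strand, list(t.exons))
        cds = extract_cds(genome, est)
        # the truth transcript IS a complete ORF, so the CDS must equal it
        assert cds is not None
        assert cds.exons == t.exons


class TestMod3:
    def test_hand_counts(self):
        assert mod3_profile([9, 12, 10, 11]) == (0.5, 0.25, 0.25)
        assert mod3_profile([30, 30, 30]) == (1.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mod3_profile([])

    @given(st.lists(st.integers(20, 5000), min_size=1, max_size=200))
    def test_fractions_sum_to_one(self, lengths):
        f = mod3_profile(lengths)
        assert sum(f) == pytest.approx(1.0)
        assert all(0 <= x <= 1 for x in f)
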