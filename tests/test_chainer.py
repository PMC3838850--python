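import numpy as np
import pytest

from conftest import CHAIN_RULES, random_chain_instance, _mk
from genechain.chainer import (
    EvidenceIntron,
    GeneModelRules,
    JoinIndex,
    assemble,
    evidence_intron_count,
    inject_cds_evidence,
    objective_value,
    oracle_assemble,
    validate_evidence,
)
from genechain.formats_io import GenomeSequence, TranscriptRecord

BIG = 1e6


def structures(preds):
    return [
        (t.strand, tuple(t.exon_intervals))
        for g in preds for t in g.transcripts
    ]


class TestValidateEvidence:
    def setup_method(self):
        self.genome = GenomeSequence("chr", "A" * 1000)
        self.rules = GeneModelRules(min_intron_len=20, max_intron_len=300)

    def test_short_intron_rejected_with_reason(self):
        acc, rej = validate_evidence(
            [EvidenceIntron("chr", 10, 11, "+")], self.genome, self.rules
        )
        assert acc == [] and rej[0][1] == "below min_intron_len"

    def test_duplicates_merge_support(self):
        acc, rej = validate_evidence(
            [EvidenceIntron("chr", 201, 300, "+", support=1),
             EvidenceIntron("chr", 201, 300, "+", support=1)],
            self.genome, self.rules,
        )
        assert len(acc) == 1 and acc[0].support == 2 and not rej

    def test_valid_intron_passes_unchanged(self):
        acc, _ = validate_evidence(
            [EvidenceIntron("chr", 201, 300, "+")], self.genome, self.rules
        )
        assert (acc[0].start, acc[0].end, acc[0].strand) == (201, 300, "+")

    def test_out_of_genome_and_strandless_rejected(self):
        acc, rej = validate_evidence(
            [EvidenceIntron("chr", 900, 1100, "+"),
             EvidenceIntron("chr", 100, 200, ".")],
            self.genome, self.rules,
        )
        assert acc == [] and len(rej) == 2


class TestAssembleBasics:
    def test_empty_candidates(self):
        assert assemble([], [], CHAIN_RULES) == []

    def test_single_exon_gene(self):
        c = _mk("chr", 100, 250, "+", "Single", 0, 5.0)
        preds = assemble([c], [], CHAIN_RULES)
        assert structures(preds) == [("+", ((100, 250),))]

    def test_negative_single_not_predicted(self):
        c = _mk("chr", 100, 250, "+", "Single", 0, -5.0)
        assert assemble([c], [], CHAIN_RULES) == []

    def test_frame_incompatible_join_refused(self):
        f = _mk("chr", 100, 200, "+", "First", 0, 10.0)
        r = f.remainder
        # terminal lengths chosen so (length - frame) % 3 == 0
        len_ok = next(n for n in range(99, 103) if (n - r) % 3 == 0)
        len_bad = next(n for n in range(99, 103)
                       if (n - (r + 1) % 3) % 3 == 0)
        t_ok = _mk("chr", 301, 300 + len_ok, "+", "Terminal", r, 10.0)
        t_bad = _mk("chr", 301, 300 + len_bad, "+", "Terminal",
                    (r + 1) % 3, 50.0)
        preds = assemble([f, t_ok, t_bad], [], CHAIN_RULES)
        # the higher-scoring terminal is frame-incompatible and refused
        assert structures(preds) == [("+", ((100, 200), (301, 300 + len_ok)))]

    def test_intron_length_bounds_respected(self):
        f = _mk("chr", 100, 200, "+", "First", 0, 10.0)
        far = _mk("chr", 5000, 5100, "+", "Terminal",
                  (3 - (101 % 3)) % 3, 10.0)
        preds = assemble([f, far], [], CHAIN_RULES)  # gap > max_intron_len
        assert all(len(t.exons) == 1 for g in preds for t in g.transcripts) \
            or preds == []

    def test_evidence_anchors_low_scoring_exon(self):
        """A lower-scoring first exon whose donor matches an evidence
        intron displaces the higher-scoring alternative."""
        orange = _mk("chr", 100, 220, "+", "First", 0, 9.0)
        blue = _mk("chr", 120, 199, "+", "First", 0, 3.0)

        def terminal(frame, score):
            length = next(n for n in range(99, 103) if (n - frame) % 3 == 0)
            return _mk("chr", 300, 299 + length, "+", "Terminal", frame, score)

        term_o = terminal(orange.remainder, 6.0)
        term_b = terminal(blue.remainder, 4.0)
        cands = [orange, blue, term_o, term_b]
        ev = [EvidenceIntron("chr", blue.end + 1, 299, "+")]
        # without evidence the orange chain wins on score (15 vs 7)
        no_ev = assemble(cands, [], CHAIN_RULES, BIG)
        assert structures(no_ev)[0][1][0] == (100, 220)
        # with the evidence intron, the blue chain is anchored in
        with_ev = assemble(cands, ev, CHAIN_RULES, BIG)
        assert structures(with_ev)[0][1][0] == (120, 199)
        assert with_ev[0].transcripts[0].evidence_intron_count == 1

    def test_nondominating_bonus_warns(self):
        c1 = _mk("chr", 100, 200, "+", "First", 0, 50.0)
        c2 = _mk("chr", 301, 400, "+", "Terminal", c1.remainder, 60.0)
        ev = [EvidenceIntron("chr", 201, 300, "+")]
        with pytest.warns(UserWarning, match="dominate"):
            assemble([c1, c2], ev, CHAIN_RULES, intron_bonus=10.0)


class TestOracleEquivalence:
    """DP vs exhaustive enumeration on random small instances."""

    def test_objective_equality_and_evidence_maximality(self):
        rng = np.random.default_rng(202)
        for _ in range(120):
            cands, ev, rules = random_chain_instance(rng)
            a = assemble(cands, ev, rules, BIG)
            o = oracle_assemble(cands, ev, rules, BIG)
            assert objective_value(a, ev, BIG) == pytest.approx(
                objective_value(o, ev, BIG), abs=1e-6
            )
            # dominant bonus => returned evidence count is maximal
            assert evidence_intron_count(a, ev) == \
                evidence_intron_count(o, ev)

    def test_join_index_path_is_equivalent(self):
        rng = np.random.default_rng(77)
        for _ in range(40):
            cands, ev, rules = random_chain_instance(rng)
            ji = JoinIndex(cands, rules)
            plain = assemble(cands, ev, rules, BIG)
            cached = assemble(cands, ev, rules, BIG, join_index=ji)
            assert structures(plain) == structures(cached)

    def test_monotone_in_evidence(self):
        """Adding an evidence intron never decreases the matched count."""
        rng = np.random.default_rng(55)
        checked = 0
        for _ in range(60):
            cands, ev, rules = random_chain_instance(rng)
            if not ev:
                continue
            base = evidence_intron_count(
                assemble(cands, ev[:-1], rules, BIG), ev[:-1]
            )
            more = evidence_intron_count(
                assemble(cands, ev, rules, BIG), ev
            )
            assert more >= base
            checked += 1
        assert checked >= 20

    def test_oracle_refuses_large_instances(self):
        cands = [_mk("chr", 1 + i * 500, 100 + i * 500, "+", "Single", 0, 1.0)
                 for i in range(16)]
        with pytest.raises(ValueError):
            oracle_assemble(cands, [], CHAIN_RULES)


class TestReduction:
    def test_no_evidence_equals_zero_bonus(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            cands, ev, rules = random_chain_instance(rng)
            zero_bonus = assemble(cands, ev, rules, intron_bonus=0.0)
            no_ev = assemble(cands, [], rules, intron_bonus=BIG)
            assert structures(zero_bonus) == structures(no_ev)
            assert objective_value(zero_bonus, [], 0.0) == pytest.approx(
                objective_value(oracle_assemble(cands, [], rules, 0.0), [], 0.0),
                abs=1e-6,
            )


class TestStrandMirror:
    def test_assembly_mirrors_under_reflection(self):
        rng = np.random.default_rng(13)
        L = 20_000
        for _ in range(30):
            cands, ev, rules = random_chain_instance(rng)

            def reflect_c(c):
                return _mk(c.seqid, L - c.end + 1, L - c.start + 1,
                           "-" if c.strand == "+" else "+",
                           c.exon_class, c.frame, c.score)

            rcands = [reflect_c(c) for c in cands]
            rev = [EvidenceIntron(e.seqid, L - e.end + 1, L - e.start + 1,
                                  "-" if e.strand == "+" else "+")
                   for e in ev]
            fwd = assemble(cands, ev, rules, BIG)
            mir = assemble(rcands, rev, rules, BIG)
            fwd_set = sorted(
                (t.strand, tuple(t.exon_intervals))
                for g in fwd for t in g.transcripts
            )
            mir_reflected = sorted(
                ("-" if t.strand == "+" else "+",
                 tuple(sorted((L - e + 1, L - s + 1)
                              for s, e in t.exon_intervals)))
                for g in mir for t in g.transcripts
            )
            assert fwd_set == mir_reflected


class TestInjectCdsEvidence:
    def cds(self, exons, strand="+", tid="t1"):
        return TranscriptRecord(tid, "chr", strand, exons, source="cds")

    def test_empty_cds_set_is_identity(self):
        c = _mk("chr", 1, 99, "+", "Single", 0, 1.0)
        aug, ev, rej = inject_cds_evidence([], [c], boost=10.0)
        assert aug == [c] and ev == [] and rej == []

    def test_two_exon_cds_adds_candidates_and_intron(self):
        t = self.cds([(100, 199), (300, 401)])  # 100+102 = 202... not %3
        t2 = self.cds([(100, 201), (300, 400)])  # 102+101 -> not %3
        ok = self.cds([(100, 201), (300, 402)])  # 102+103... no
        good = self.cds([(100, 201), (300, 401)])  # 102 + 102 = 204 ok
        aug, ev, rej = inject_cds_evidence([good], [], boost=10.0)
        assert len(aug) == 2 and len(ev) == 1
        assert {c.exon_class for c in aug} == {"First", "Terminal"}
        assert (ev[0].start, ev[0].end) == (202, 299)
        first = next(c for c in aug if c.exon_class == "First")
        assert first.frame == 0 and first.score == 10.0
        term = next(c for c in aug if c.exon_class == "Terminal")
        assert term.frame == first.remainder

    def test_frame_violation_rejected(self):
        bad = self.cds([(100, 199)])  # 100 bases, not a codon multiple
        aug, ev, rej = inject_cds_evidence([bad], [], boost=1.0)
        assert aug == [] and rej[0][1].startswith("CDS length")

    def test_duplicate_candidate_boosted_not_duplicated(self):
        exist = _mk("chr", 100, 201, "+", "First", 0, 3.0)
        term = _mk("chr", 300, 401, "+", "Terminal", exist.remainder, 3.0)
        good = self.cds([(100, 201), (300, 401)])
        aug, ev, _ = inject_cds_evidence([good], [exist, term], boost=50.0)
        assert len(aug) == 2
        assert all(c.score == 50.0 for c in aug)

    def test_minus_strand_classes(self):
        good = self.cds([(100, 201), (300, 401)], strand="-")
        aug, ev, rej = inject_cds_evidence([good], [], boost=5.0)
        by_class = {c.exon_class: c for c in aug}
        assert by_class["First"].start == 300  # 5'-most on minus strand
        assert by_class["Terminal"].start == 100
        assert not rej
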