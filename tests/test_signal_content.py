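import math

import numpy as np
import pytest

from genechain.formats_io import GenomeSequence
from genechain.signal_content import (
    CodingModel,
    ModelParams,
    Pwm,
    load_params,
    save_params,
    score_coding,
    score_pwm,
    train_coding_model,
    train_pwm,
)

UNIFORM = {b: 0.25 for b in "ACGT"}


class TestTrainPwm:
    def test_pure_column_closed_form(self):
        pwm = train_pwm(["GT", "GT"], "custom", UNIFORM, pseudocount=0.0)
        assert pwm.log_odds[0, 2] == pytest.approx(2.0)  # log2(1/0.25)
        assert pwm.log_odds[1, 3] == pytest.approx(2.0)

    def test_uniform_columns_give_zero(self):
        pwm = train_pwm(["AA", "CC", "GG", "TT"], "custom", UNIFORM, 0.0)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_pseudocount_hand_formula(self):
        # pos2 A: log2(((1+1)/(2+4)) / 0.25)
        pwm = train_pwm(["GA", "GC"], "custom", UNIFORM, pseudocount=1.0)
        assert pwm.log_odds[1, 0] == pytest.approx(math.log2((2 / 6) / 0.25))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            train_pwm([], "custom")
        with pytest.raises(ValueError):
            train_pwm(["GT", "GTA"], "custom")
        with pytest.raises(ValueError):
            train_pwm(["GN"], "custom")

    def test_geometry_enforced_for_known_kinds(self):
        with pytest.raises(ValueError, match="length 9"):
            train_pwm(["GT"], "donor")


class TestScorePwm:
    def test_zero_pwm_scores_zero_everywhere(self):
        pwm = Pwm("custom", offset=1, width=3, core="",
                  log_odds=np.zeros((3, 4)))
        g = GenomeSequence("s", "ACGTACGT")
        for pos in range(2, 8):
            assert score_pwm(pwm, g, pos) == 0.0

    def test_self_score_is_maximal(self):
        window = "CAGGTAAGT"
        pwm = train_pwm([window], "donor", UNIFORM, pseudocount=0.1)
        g = GenomeSequence("s", "AAAA" + window + "AAAA")
        got = score_pwm(pwm, g, 4 + 3 + 1)  # core G position
        assert got == pytest.approx(pwm.max_score())

    def test_out_of_bounds_returns_none(self):
        pwm = train_pwm(["CAGGTAAGT"], "donor", UNIFORM, 0.5)
        g = GenomeSequence("s", "CAGGTAAGT")
        assert score_pwm(pwm, g, 1) is None

    def test_window_with_n_returns_none(self):
        pwm = train_pwm(["CAGGTAAGT"], "donor", UNIFORM, 0.5)
        g = GenomeSequence("s", "AAAACANGTAAGTAAAA")
        assert score_pwm(pwm, g, 8) is None

    def test_strand_symmetry(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        g = GenomeSequence("s", seq)
        grc = GenomeSequence("s", g.revcomp)
        pwm = train_pwm(["CAGGTAAGT", "AAGGTGAGT"], "donor", UNIFORM, 0.5)
        L = g.length
        for pos in range(5, 55):
            fwd = score_pwm(pwm, grc, pos, "+")
            mirror = score_pwm(pwm, g, L - pos + 1, "-")
            assert (fwd is None and mirror is None) or \
                fwd == pytest.approx(mirror)


def toy_coding_model(order=0):
    rng = np.random.default_rng(3)
    cds = ["".join(rng.choice(list("ACGT"), p=[0.4, 0.3, 0.2, 0.1], size=300))
           for _ in range(4)]
    bg = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(3)]
    return train_coding_model(cds, bg, order=order, pseudocount=0.5)


class TestCodingModel:
    def test_identical_training_sets_score_zero(self):
        seqs = ["ATGGCCAAATAGATGGCCAAATAG" * 4]
        model = train_coding_model(seqs, seqs, order=0, pseudocount=0.0)
        g = GenomeSequence("s", "ACGTTGCAACGT")
        # identical coding and background chains: frame-averaged signal is
        # zero only when the CDS has no frame structure; with order 0 and a
        # shared training set each frame sees the same marginal only if the
        # sequence is frame-symmetric, so test the exact invariant instead:
        # background == frame-pooled coding distribution
        pooled = (2.0 ** model.coding_logp).mean(axis=0)
        bg = 2.0 ** model.background_logp
        assert np.allclose(pooled.sum(axis=-1), 1.0)
        assert np.allclose(bg.sum(axis=-1), 1.0)

    def test_order0_all_A_cds_closed_form(self):
        model = train_coding_model(["AAA" * 10], ["ACGT" * 30], order=0,
                                   pseudocount=1.0)
        # per frame: 10 A observations -> P(A|frame) = (10+1)/(10+4);
        # background: 30 A of 120 -> P(A) = (30+1)/(120+4)
        expect = math.log2((11 / 14)) - math.log2((31 / 124))
        g = GenomeSequence("s", "A" * 9)
        got = score_coding(model, g, 1, 9, "+", 0)
        assert got == pytest.approx(9 * expect)

    def test_order1_hand_tally_on_printed_cds(self):
        cds = "ATGGCCAAATAG"
        model = train_coding_model([cds], ["ACGT" * 10], order=1,
                                   pseudocount=0.0)
        # transitions by phase of the target base (phase = index % 3):
        # e.g. phase-0 targets: G@3(ctx G), A@6(ctx C), T@9(ctx A)
        probs = 2.0 ** model.coding_logp
        G, A, C, T = 2, 0, 1, 3
        assert probs[0, G, A] == pytest.approx(0.0)   # G->G only at phase 0
        assert probs[0, C, A] == pytest.approx(1.0)   # C->A at phase 0
        assert probs[0, A, T] == pytest.approx(1.0)   # A->T at phase 0
        assert probs[1, A, A] == pytest.approx(0.5)   # A->{A,T} at phase 1
        assert probs[1, A, T] == pytest.approx(0.5)
        assert probs[2, A, A] == pytest.approx(0.5)   # A->{A,G} at phase 2
        assert probs[2, A, G] == pytest.approx(0.5)

    def test_additivity_across_split(self):
        model = toy_coding_model(order=0)
        rng = np.random.default_rng(9)
        g = GenomeSequence("s", "".join(rng.choice(list("ACGT"), size=90)))
        total = score_coding(model, g, 11, 70, "+", 1)
        left = score_coding(model, g, 11, 40, "+", 1)
        ln = 40 - 11 + 1
        f2 = (3 - ((ln - 1) % 3)) % 3
        right = score_coding(model, g, 41, 70, "+", f2)
        assert total == pytest.approx(left + right)

    def test_order0_matches_bruteforce(self):
        model = toy_coding_model(order=0)
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=50))
        g = GenomeSequence("s", seq)
        code = {b: i for i, b in enumerate("ACGT")}
        for frame in (0, 1, 2):
            expect = 0.0
            for i, b in enumerate(seq[4:30]):  # i counts from interval start
                phase = (i - frame) % 3
                expect += (model.coding_logp[phase, 0, code[b]]
                           - model.background_logp[0, code[b]])
            got = score_coding(model, g, 5, 30, "+", frame)
            assert got == pytest.approx(expect)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            train_coding_model([], ["ACGT"], order=0)
        with pytest.raises(ValueError):
            train_coding_model(["ACGT"], ["ACGT"], order=0)  # len % 3 != 0
        with pytest.raises(ValueError):
            train_coding_model(["ACG"], ["ACGT"], order=-1)
        model = toy_coding_model()
        g = GenomeSequence("s", "ACGT")
        with pytest.raises(ValueError):
            score_coding(model, g, 1, 10, "+", 0)


class TestParamsRoundTrip:
    def test_lossless_round_trip(self, tmp_path, sim_world):
        params = sim_world["params"]
        p = tmp_path / "params.ini"
        save_params(params, p)
        back = load_params(p)
        for kind in ("donor", "acceptor", "start"):
            assert np.array_equal(back.pwms[kind].log_odds,
                                  params.pwms[kind].log_odds)
            assert back.pwms[kind].offset == params.pwms[kind].offset
        assert np.array_equal(back.coding.coding_logp,
                              params.coding.coding_logp)
        assert np.array_equal(back.coding.background_logp,
                              params.coding.background_logp)
        assert back.exon_weight == params.exon_weight
        assert back.exon_score_threshold == params.exon_score_threshold
        assert back.intron_bonus == params.intron_bonus
        assert back.signal_thresholds == params.signal_thresholds
        assert back.gene_model == params.gene_model

    def test_missing_pwm_section_named(self, tmp_path, sim_world):
        p = tmp_path / "params.ini"
        save_params(sim_world["params"], p)
        text = p.read_text()
        text = text.replace("[pwm.donor]", "[pwm.gone]")
        p.write_text(text)
        with pytest.raises(ValueError, match="missing pwm: donor"):
            load_params(p)

    def test_negative_intron_bonus_rejected(self, tmp_path, sim_world):
        p = tmp_path / "params.ini"
        save_params(sim_world["params"], p)
        text = p.read_text().replace("intron_bonus = 1000000.0",
                                     "intron_bonus = -5.0")
        p.write_text(text)
        with pytest.raises(ValueError, match="validation"):
            load_params(p)

    def test_modelparams_requires_all_pwms(self, sim_world):
        params = sim_world["params"]
        pwms = dict(params.pwms)
        pwms.pop("acceptor")
        with pytest.raises(ValueError, match="missing pwm: acceptor"):
            ModelParams(pwms=pwms, coding=params.coding)
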