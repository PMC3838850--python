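"""Statistical models for splice/translation signals and coding potential.

Signals (donor GT, acceptor AG, translation start ATG) are scored with
position weight matrices (PWMs) holding log2 odds against a background base
composition.  Coding potential is a frame-specific Markov chain
log-likelihood ratio against a single background chain.  Stop codons are
matched exactly ({TAA, TAG, TGA}) and carry no PWM.

Context convention for the coding model: the order-k context of a scored
base is the k genomic bases immediately 5' of it on the same strand, even
when those bases lie outside the scored interval; positions without a full
context (sequence start) or with N in the window contribute zero.  This
makes interval scores exactly additive and lets exon enumeration use
cumulative per-phase score arrays that agree with :func:`score_coding` to
floating-point roundoff.
"""

from __future__ import annotations

import configparser
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .chainer import DEFAULT_INTRON_BONUS, GeneModelRules

__all__ = [
    "Pwm",
    "CodingModel",
    "ModelParams",
    "SIGNAL_GEOMETRY",
    "STOP_CODONS",
    "train_pwm",
    "score_pwm",
    "train_coding_model",
    "score_coding",
    "save_params",
    "load_params",
    "encode_seq",
    "coding_llr_track",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# signal_kind -> (offset: context bases upstream of the core's first base,
#                 width: total window length, core consensus string)
SIGNAL_GEOMETRY = {
    "donor": (3, 9, "GT"),       # 3 exonic + GT + 4 more intronic
    "acceptor": (18, 23, "AG"),  # 18 intronic + AG + 3 exonic
    "start": (6, 12, "ATG"),     # 6 upstream + ATG + 3 coding
}

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

UNIFORM_BG = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}


def encode_seq(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3, anything else -> 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class Pwm:
    signal_kind: str
    offset: int
    width: int
    core: str
    log_odds: np.ndarray  # (width, 4), log2(p_position / p_background)

    def __post_init__(self):
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        if self.log_odds.shape != (self.width, 4):
            raise ValueError(
                f"log_odds shape {self.log_odds.shape} != ({self.width}, 4)"
            )

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass
class CodingModel:
    """Frame-specific order-k Markov chain vs a single background chain."""

    order: int
    coding_logp: np.ndarray      # (3, 4**order, 4) log2 transition probs
    background_logp: np.ndarray  # (4**order, 4)
    pseudocount: float

    def __post_init__(self):
        k = self.order
        self.coding_logp = np.asarray(self.coding_logp, dtype=float)
        self.background_logp = np.asarray(self.background_logp, dtype=float)
        if self.coding_logp.shape != (3, 4 ** k, 4):
            raise ValueError("coding_logp has wrong shape for order")
        if self.background_logp.shape != (4 ** k, 4):
            raise ValueError("background_logp has wrong shape for order")


DEFAULT_SIGNAL_THRESHOLDS = {"donor": 0.0, "acceptor": 0.0, "start": 0.0}


@dataclass
class ModelParams:
    """Everything the predictor needs, trainable and serializable."""

    pwms: dict[str, Pwm]
    coding: CodingModel
    # exon_weight is added to every candidate's score (the classic exon-
    # weight calibration): it prices the inclusion of an exon so that weak
    # standalone chains score negative and drop out of the optimal structure
    # set, while weak true exons can still be rescued by their chain context.
    exon_weight: float = -12.0
    exon_score_threshold: float = -25.0
    intron_bonus: float = DEFAULT_INTRON_BONUS
    signal_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_THRESHOLDS)
    )
    gene_model: GeneModelRules = field(default_factory=GeneModelRules)
    top_k_per_class: int | None = None

    def __post_init__(self):
        for kind in ("donor", "acceptor", "start"):
            if kind not in self.pwms:
                raise ValueError(f"missing pwm: {kind}")
        if self.intron_bonus < 0:
            raise ValueError("intron_bonus must be >= 0")


def _background_vector(background) -> np.ndarray:
    if background is None:
        background = UNIFORM_BG
    bg = np.array([background[b] for b in "ACGT"], dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be positive")
    return bg / bg.sum()


def train_pwm(aligned_windows, signal_kind, background=None,
              pseudocount: float = 0.5, offset: int | None = None) -> Pwm:
    """Estimate a PWM from aligned equal-length training windows.

    log_odds[i][b] = log2( (count[i][b] + pc) / (n + 4*pc) / background[b] ).
    """
    if not aligned_windows:
        raise ValueError("empty PWM training set")
    width = len(aligned_windows[0])
    if any(len(w) != width for w in aligned_windows):
        raise ValueError("PWM training windows have unequal lengths")
    geom = SIGNAL_GEOMETRY.get(signal_kind)
    if geom is not None:
        g_offset, g_width, core = geom
        if width != g_width:
            raise ValueError(
                f"{signal_kind} windows must have length {g_width}, got {width}"
            )
        if offset is None:
            offset = g_offset
    else:
        core = ""
        if offset is None:
            offset = 0
    bg = _background_vector(background)
    counts = np.zeros((width, 4), dtype=float)
    for w in aligned_windows:
        enc = encode_seq(w)
        if np.any(enc > 3):
            raise ValueError(f"PWM training window contains non-ACGT: {w!r}")
        counts[np.arange(width), enc] += 1.0
    n = len(aligned_windows)
    probs = (counts + pseudocount) / (n + 4.0 * pseudocount)
    with np.errstate(divide="ignore"):
        log_odds = np.log2(probs / bg[None, :])
    return Pwm(signal_kind=signal_kind, offset=offset, width=width,
               core=core, log_odds=log_odds)


def score_pwm(pwm: Pwm, genome, pos: int, strand: str = "+") -> float | None:
    """Score the PWM window anchored with the core's first base at ``pos``.

    ``pos`` is the 1-based forward-strand coordinate of the core's first
    base in transcript orientation (for the reverse strand this is the
    highest forward coordinate of the core).  Returns None (no signal) when
    the window runs out of bounds or contains N.
    """
    L = genome.length
    if strand == "-":
        seq = genome.revcomp
        p = L - pos + 1
    else:
        seq = genome.seq
        p = pos
    lo = p - pwm.offset  # 1-based window start
    hi = lo + pwm.width - 1
    if lo < 1 or hi > L:
        return None
    window = seq[lo - 1 : hi]
    if "N" in window:
        return None
    enc = encode_seq(window)
    return float(pwm.log_odds[np.arange(pwm.width), enc].sum())


def _context_indices(enc: np.ndarray, order: int):
    """Context index and validity mask for every position of ``enc``.

    ctx[p] encodes enc[p-order..p-1]; valid[p] is False for p < order or any
    N inside enc[p-order..p].
    """
    L = len(enc)
    ctx = np.zeros(L, dtype=np.int64)
    valid = enc <= 3
    safe = np.where(enc <= 3, enc, 0)
    for j in range(1, order + 1):
        shifted = np.zeros(L, dtype=np.int64)
        shifted[j:] = safe[:-j]
        ctx = ctx * 1 + shifted * (4 ** (j - 1))
        ok = np.zeros(L, dtype=bool)
        ok[j:] = enc[:-j] <= 3
        valid &= ok
    if order > 0:
        valid[:order] = False
    return ctx, valid


def train_coding_model(cds_seqs, noncoding_seqs, order: int = 4,
                       pseudocount: float = 0.5) -> CodingModel:
    """Train frame-specific coding vs background Markov chains.

    CDS sequences must start at codon position 0 and have length divisible
    by 3; the background chain is frame-agnostic.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if not cds_seqs or not noncoding_seqs:
        raise ValueError("empty coding-model training data")
    ncat = 4 ** order
    coding_counts = np.zeros((3, ncat, 4), dtype=float)
    bg_counts = np.zeros((ncat, 4), dtype=float)
    for seq in cds_seqs:
        if len(seq) % 3 != 0:
            raise ValueError("CDS training sequence length not divisible by 3")
        enc = encode_seq(seq)
        ctx, valid = _context_indices(enc, order)
        pos = np.nonzero(valid)[0]
        phases = pos % 3
        np.add.at(coding_counts, (phases, ctx[pos], enc[pos]), 1.0)
    for seq in noncoding_seqs:
        enc = encode_seq(seq)
        ctx, valid = _context_indices(enc, order)
        pos = np.nonzero(valid)[0]
        np.add.at(bg_counts, (ctx[pos], enc[pos]), 1.0)

    def _logp(counts):
        tot = counts.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            probs = (counts + pseudocount) / (tot + 4.0 * pseudocount)
            # contexts never observed (and unsmoothed) are unusable; park
            # them at -inf so accidental use is loud rather than silent
            return np.where(np.isnan(probs), -np.inf, np.log2(probs))

    return CodingModel(order=order, coding_logp=_logp(coding_counts),
                       background_logp=_logp(bg_counts),
                       pseudocount=pseudocount)


def coding_llr_track(model: CodingModel, enc: np.ndarray) -> np.ndarray:
    """Per-base log2 coding/background ratio for each codon phase.

    Returns an array of shape (3, L): row ``ph`` holds the contribution of
    each base assuming it sits at codon position ``ph``.  Invalid positions
    (missing context, N) are zero.
    """
    L = len(enc)
    ctx, valid = _context_indices(enc, model.order)
    out = np.zeros((3, L), dtype=float)
    pos = np.nonzero(valid)[0]
    if len(pos) == 0:
        return out
    bg = model.background_logp[ctx[pos], enc[pos]]
    for ph in range(3):
        out[ph, pos] = model.coding_logp[ph, ctx[pos], enc[pos]] - bg
    return out


def score_coding(model: CodingModel, genome, start: int, end: int,
                 strand: str = "+", frame: int = 0) -> float:
    """Log2 coding/background score of [start, end] read in ``frame``.

    ``frame`` is the phase of the interval's first (5') base: the number of
    bases that complete the codon begun upstream; codons start at offsets
    frame, frame+3, ... within the interval.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    L = genome.length
    if start < 1 or end > L or start > end:
        raise ValueError(f"interval ({start},{end}) out of bounds")
    if strand == "-":
        seq = genome.revcomp
        s = L - end + 1
        e = L - start + 1
    else:
        seq = genome.seq
        s, e = start, end
    k = model.order
    ext_lo = max(1, s - k)  # include upstream context
    enc = encode_seq(seq[ext_lo - 1 : e])
    llr = coding_llr_track(model, enc)
    off = s - ext_lo  # index of interval start within enc
    idx = np.arange(off, off + (e - s + 1))
    phases = (np.arange(e - s + 1) - frame) % 3
    return float(llr[phases, idx].sum())


# ---------------------------------------------------------------------------
# parameter file round-trip


def _pwm_to_section(pwm: Pwm) -> dict:
    return {
        "signal_kind": pwm.signal_kind,
        "offset": str(pwm.offset),
        "width": str(pwm.width),
        "core": pwm.core,
        "log_odds": json.dumps(pwm.log_odds.tolist()),
    }


def _pwm_from_section(sec) -> Pwm:
    return Pwm(
        signal_kind=sec["signal_kind"],
        offset=int(sec["offset"]),
        width=int(sec["width"]),
        core=sec["core"],
        log_odds=np.array(json.loads(sec["log_odds"]), dtype=float),
    )


def save_params(params: ModelParams, path) -> None:
    """Write ModelParams to a sectioned text file (lossless round-trip)."""
    cp = configparser.ConfigParser(interpolation=None)
    for kind in ("donor", "acceptor", "start"):
        cp[f"pwm.{kind}"] = _pwm_to_section(params.pwms[kind])
    cp["coding"] = {
        "order": str(params.coding.order),
        "pseudocount": repr(params.coding.pseudocount),
        "coding_logp": json.dumps(params.coding.coding_logp.tolist()),
        "background_logp": json.dumps(params.coding.background_logp.tolist()),
    }
    gm = params.gene_model
    cp["gene_model"] = {
        "allowed_transitions": json.dumps(sorted(list(t) for t in gm.allowed_transitions)),
        "min_intron_len": str(gm.min_intron_len),
        "max_intron_len": str(gm.max_intron_len),
        "min_intergenic": str(gm.min_intergenic),
        "min_exon_len": str(gm.min_exon_len),
        "max_exon_len": str(gm.max_exon_len),
        "allow_partial_genes": str(gm.allow_partial_genes),
    }
    cp["chaining"] = {
        "exon_weight": repr(params.exon_weight),
        "exon_score_threshold": repr(params.exon_score_threshold),
        "intron_bonus": repr(params.intron_bonus),
        "signal_thresholds": json.dumps(params.signal_thresholds),
        "top_k_per_class": json.dumps(params.top_k_per_class),
    }
    with open(path, "w") as fh:
        cp.write(fh)


def load_params(path) -> ModelParams:
    cp = configparser.ConfigParser(interpolation=None)
    with open(path) as fh:
        cp.read_file(fh)
    pwms = {}
    for kind in ("donor", "acceptor", "start"):
        sec = f"pwm.{kind}"
        if sec not in cp:
            raise ValueError(f"missing pwm: {kind}")
        pwms[kind] = _pwm_from_section(cp[sec])
    for sec in ("coding", "gene_model", "chaining"):
        if sec not in cp:
            raise ValueError(f"missing section: {sec}")
    csec = cp["coding"]
    coding = CodingModel(
        order=int(csec["order"]),
        coding_logp=np.array(json.loads(csec["coding_logp"]), dtype=float),
        background_logp=np.array(json.loads(csec["background_logp"]), dtype=float),
        pseudocount=float(csec["pseudocount"]),
    )
    g = cp["gene_model"]
    gene_model = GeneModelRules(
        allowed_transitions=frozenset(
            tuple(t) for t in json.loads(g["allowed_transitions"])
        ),
        min_intron_len=int(g["min_intron_len"]),
        max_intron_len=int(g["max_intron_len"]),
        min_intergenic=int(g["min_intergenic"]),
        min_exon_len=int(g["min_exon_len"]),
        max_exon_len=int(g["max_exon_len"]),
        allow_partial_genes=g["allow_partial_genes"] == "True",
    )
    ch = cp["chaining"]
    intron_bonus = float(ch["intron_bonus"])
    if intron_bonus < 0:
        raise ValueError("validation error: intron_bonus must be >= 0")
    return ModelParams(
        pwms=pwms,
        coding=coding,
        exon_weight=float(ch["exon_weight"]),
        exon_score_threshold=float(ch["exon_score_threshold"]),
        intron_bonus=intron_bonus,
        signal_thresholds={
            k: float(v) for k, v in json.loads(ch["signal_thresholds"]).items()
        },
        gene_model=gene_model,
        top_k_per_class=json.loads(ch["top_k_per_class"]),
    )
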