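"""Enumerate and score candidate coding exons from detected signals.

Four exon classes are produced, bounded by signal pairs:

* First:    translation start .. donor
* Internal: acceptor .. donor
* Terminal: acceptor .. stop codon (stop included in the exon)
* Single:   translation start .. stop codon

A candidate's score is the sum of its two boundary signal scores and the
coding-model log-likelihood ratio of its interval read in its frame (stop
codons score zero as signals).  Candidates containing an in-frame stop codon
strictly inside the reading are never produced; a stop codon assembled
across an intron junction is not checked (documented limitation of the
linear-join chaining model).

All enumeration runs in strand-apparent coordinates (the reverse complement
for the minus strand) and results are reflected back to forward-strand
coordinates at the end.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .signal_content import (
    STOP_CODONS,
    ModelParams,
    coding_llr_track,
    encode_seq,
)

__all__ = [
    "SignalSite",
    "ExonCandidate",
    "find_signals",
    "enumerate_exons",
    "top_k_filter",
    "build_candidates",
]

EXON_CLASSES = ("First", "Internal", "Terminal", "Single")


@dataclass
class SignalSite:
    """A scored signal; pos is the forward-strand coordinate of the core's
    first base in transcript orientation."""

    kind: str
    pos: int
    strand: str
    score: float


@dataclass
class ExonCandidate:
    """A typed, scored, frame-annotated genomic interval (forward coords)."""

    seqid: str
    start: int
    end: int
    strand: str
    exon_class: str
    frame: int
    score: float
    five_site: SignalSite | None = None
    three_site: SignalSite | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def remainder(self) -> int:
        """Phase carried into the downstream intron: a donor-side exon with
        remainder r joins an acceptor-side exon with frame r."""
        return (3 - ((self.length - self.frame) % 3)) % 3

    @property
    def key(self) -> tuple:
        return (self.seqid, self.start, self.end, self.strand,
                self.exon_class, self.frame)


def _core_positions(enc: np.ndarray, core: str) -> np.ndarray:
    """1-based apparent positions where ``core`` occurs exactly."""
    L = len(enc)
    n = len(core)
    if L < n:
        return np.empty(0, dtype=np.int64)
    mask = np.ones(L - n + 1, dtype=bool)
    core_enc = encode_seq(core)
    for j, b in enumerate(core_enc):
        mask &= enc[j : L - n + 1 + j] == b
    return np.nonzero(mask)[0] + 1


def _score_windows(pwm, enc: np.ndarray, positions: np.ndarray):
    """PWM scores of windows anchored at ``positions`` (apparent coords).

    Returns (kept_positions, scores); out-of-bounds or N-containing windows
    are dropped.
    """
    if len(positions) == 0:
        return positions, np.empty(0)
    L = len(enc)
    lo = positions - pwm.offset
    ok = (lo >= 1) & (lo + pwm.width - 1 <= L)
    positions, lo = positions[ok], lo[ok]
    if len(positions) == 0:
        return positions, np.empty(0)
    win = enc[(lo[:, None] - 1) + np.arange(pwm.width)[None, :]]
    good = ~np.any(win > 3, axis=1)
    positions, win = positions[good], win[good]
    scores = pwm.log_odds[np.arange(pwm.width)[None, :], win].sum(axis=1)
    return positions, scores


def _apparent_signals(genome, params: ModelParams, strand: str):
    """Signal positions and scores in strand-apparent coordinates."""
    seq = genome.seq if strand == "+" else genome.revcomp
    enc = encode_seq(seq)
    out = {}
    for kind in ("donor", "acceptor", "start"):
        pwm = params.pwms[kind]
        positions = _core_positions(enc, pwm.core)
        positions, scores = _score_windows(pwm, enc, positions)
        thr = params.signal_thresholds.get(kind, 0.0)
        keep = scores >= thr
        out[kind] = (positions[keep], scores[keep])
    stops = np.concatenate(
        [_core_positions(enc, c) for c in STOP_CODONS]
        or [np.empty(0, dtype=np.int64)]
    )
    stops.sort()
    out["stop"] = (stops, np.zeros(len(stops)))
    return enc, out


def _to_forward(pos_app: int, L: int, strand: str) -> int:
    return pos_app if strand == "+" else L - pos_app + 1


def find_signals(genome, params: ModelParams, strand: str = "+"):
    """All signal sites above their per-kind thresholds, as forward coords."""
    L = genome.length
    _, app = _apparent_signals(genome, params, strand)
    result: dict[str, list[SignalSite]] = {}
    for kind, (positions, scores) in app.items():
        sites = [
            SignalSite(kind, _to_forward(int(p), L, strand), strand, float(s))
            for p, s in zip(positions, scores)
        ]
        sites.sort(key=lambda s: s.pos)
        result[kind] = sites
    return result


def enumerate_exons(signals, genome, params: ModelParams, strand: str = "+"):
    """All admissible exon candidates from the given signal sites.

    ``signals`` is the mapping returned by :func:`find_signals` (forward
    coordinates); output candidates carry forward coordinates too.
    """
    L = genome.length
    seq = genome.seq if strand == "+" else genome.revcomp
    enc = encode_seq(seq)
    rules = params.gene_model
    min_len, max_len = rules.min_exon_len, rules.max_exon_len
    thr = params.exon_score_threshold
    weight = params.exon_weight

    # strand-apparent site lists
    def app_sites(kind):
        sites = [
            (_to_forward(s.pos, L, strand), s) for s in signals.get(kind, [])
        ]
        sites.sort()
        return sites

    donors = app_sites("donor")
    acceptors = app_sites("acceptor")
    starts = app_sites("start")
    stop_positions = sorted(p for p, _ in app_sites("stop"))
    stop_site_by_pos = {p: s for p, s in app_sites("stop")}

    donor_pos = [p for p, _ in donors]

    # cumulative coding score per phase-residue class:
    # cum[r][p] = sum over q<=p of llr at q read with codon phase (q - r) % 3
    llr = coding_llr_track(params.coding, enc)
    q = np.arange(1, L + 1)
    cum = np.zeros((3, L + 1))
    for r in range(3):
        cum[r, 1:] = np.cumsum(llr[(q - r) % 3, q - 1])

    def coding_score(s, e, f):
        r = (s + f) % 3
        return float(cum[r, e] - cum[r, s - 1])

    stops_by_r = {r: [p for p in stop_positions if p % 3 == r] for r in range(3)}

    def next_stop(c0):
        arr = stops_by_r[c0 % 3]
        i = bisect_left(arr, c0)
        return arr[i] if i < len(arr) else None

    out = []

    def emit(s, e, klass, f, five, three, sc):
        sc += weight
        if sc < thr:
            return
        if strand == "+":
            fs, fe = s, e
        else:
            fs, fe = L - e + 1, L - s + 1
        out.append(
            ExonCandidate(seqid=genome.id, start=fs, end=fe, strand=strand,
                          exon_class=klass, frame=f, score=sc,
                          five_site=five, three_site=three)
        )

    def donor_range(e_min, e_max):
        """Donor sites whose exon end d-1 lies in [e_min, e_max]."""
        lo = bisect_left(donor_pos, e_min + 1)
        hi = bisect_right(donor_pos, e_max + 1)
        return donors[lo:hi]

    for a, start_site in starts:
        stop = next_stop(a)
        # First exons: start .. donor-1, frame 0, stop-free
        e_max = a + max_len - 1
        if stop is not None:
            e_max = min(e_max, stop + 1)
        e_max = min(e_max, L)
        for d, don_site in donor_range(a + min_len - 1, e_max):
            e = d - 1
            emit(a, e, "First", 0, start_site, don_site,
                 start_site.score + don_site.score + coding_score(a, e, 0))
        # Single exons: start .. first in-frame stop (included)
        if stop is not None:
            e = stop + 2
            if e <= L and min_len <= e - a + 1 <= max_len:
                three = stop_site_by_pos[stop]
                emit(a, e, "Single", 0, start_site, three,
                     start_site.score + coding_score(a, e, 0))

    for c, acc_site in acceptors:
        s = c + 2  # exon begins right after the AG
        if s > L:
            continue
        for f in (0, 1, 2):
            stop = next_stop(s + f)
            # Internal exons
            e_max = s + max_len - 1
            if stop is not None:
                e_max = min(e_max, stop + 1)
            e_max = min(e_max, L)
            for d, don_site in donor_range(s + min_len - 1, e_max):
                e = d - 1
                emit(s, e, "Internal", f, acc_site, don_site,
                     acc_site.score + don_site.score + coding_score(s, e, f))
            # Terminal exon: ends at the first in-frame stop
            if stop is not None:
                e = stop + 2
                if e <= L and min_len <= e - s + 1 <= max_len:
                    three = stop_site_by_pos[stop]
                    emit(s, e, "Terminal", f, acc_site, three,
                         acc_site.score + coding_score(s, e, f))

    out.sort(key=lambda c: (c.start, c.end, c.exon_class, c.frame))
    return out


def top_k_filter(candidates, k_per_class: int | float | None):
    """Keep the k highest-scoring candidates per exon class.

    Ties on score break by smaller start, then smaller end, then frame; the
    returned list is in stable (start, end, frame) order.
    """
    if k_per_class is None:
        return sorted(candidates,
                      key=lambda c: (c.seqid, c.start, c.end, c.frame))
    if k_per_class < 1:
        raise ValueError("k_per_class must be >= 1")
    kept = []
    by_class: dict[str, list] = {}
    for c in candidates:
        by_class.setdefault(c.exon_class, []).append(c)
    for klass in sorted(by_class):
        group = sorted(by_class[klass],
                       key=lambda c: (-c.score, c.start, c.end, c.frame))
        kept.extend(group[: int(min(k_per_class, len(group)))])
    kept.sort(key=lambda c: (c.seqid, c.start, c.end, c.frame))
    return kept


def build_candidates(genome, params: ModelParams, strands=("+", "-")):
    """Find signals and enumerate exon candidates on the given strands."""
    out = []
    for strand in strands:
        signals = find_signals(genome, params, strand)
        out.extend(enumerate_exons(signals, genome, params, strand))
    if params.top_k_per_class is not None:
        out = top_k_filter(out, params.top_k_per_class)
    out.sort(key=lambda c: (c.seqid, c.start, c.end, c.strand, c.frame))
    return out
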