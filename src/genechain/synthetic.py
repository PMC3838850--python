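"""Seeded simulator of genomes, gene structures and EST alignments.

The generator emits multi-gene genomes on both strands with codon-biased
stop-free CDS, canonical GT..AG introns carrying planted consensus splice
contexts, optional exon-skipping isoforms, and ESTs sampled as contiguous
windows of mature transcripts.  Alignments are emitted directly as exact
truth-block projections (no aligner in the loop), which keeps every
downstream stage hermetically testable; the EST error rate perturbs only
the reported identity attribute, never the block coordinates.

Same seed, same bytes: everything is driven by one numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chainer import GeneModelRules
from .formats_io import (
    GenomeSequence,
    GffFeature,
    SplicedAlignment,
    TranscriptRecord,
    transcripts_from_features,
)
from .signal_content import (
    SIGNAL_GEOMETRY,
    ModelParams,
    train_coding_model,
    train_pwm,
)

__all__ = [
    "SimConfig",
    "simulate_genome",
    "simulate_ests",
    "train_from_truth",
    "sample_intron_lengths",
    "est_sequences",
]

BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

# sense codons with a mild, fixed usage bias (GC-rich third positions and a
# few "preferred" codons get extra weight) so the coding Markov chain has
# signal to learn
_SENSE_CODONS = [
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in _STOPS
]


def _codon_weights():
    w = []
    for codon in _SENSE_CODONS:
        weight = 1.0
        if codon[2] in "GC":
            weight *= 2.0
        if codon[0] in "AG":
            weight *= 1.3
        w.append(weight)
    w = np.array(w)
    return w / w.sum()


_CODON_W = _codon_weights()

_MIN_INTERGENIC_GAP = 300
_KOZAK = "GCCACC"
_DONOR_TAIL = "AAGT"        # intron bases 3..6 after the fixed GT
_ACCEPTOR_TRACT_LEN = 9     # pyrimidine-rich bases before the CAG box
_CONSENSUS_P = 0.85


@dataclass
class SimConfig:
    genome_length: int = 100_000
    n_genes: int = 30
    exon_count_range: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (80, 250)
    intron_len_range: tuple[int, int] = (50, 200)
    isoform_prob: float = 0.2
    gc_content: float = 0.45
    est_per_gene_range: tuple[int, int] = (4, 10)
    est_len_range: tuple[int, int] = (500, 4000)
    est_error_rate: float = 0.005
    unspliced_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("exon_count_range", "exon_len_range", "intron_len_range",
                     "est_per_gene_range", "est_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid range {name}={lo, hi}")
        for name in ("isoform_prob", "est_error_rate", "unspliced_fraction",
                     "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.intron_len_range[0] < 20:
            raise ValueError("intron_len_range minimum must be >= 20 to fit "
                             "the planted splice contexts")


def _rand_seq(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)]) if n else ""


def _consensus_sample(rng, consensus: str) -> str:
    out = []
    for b in consensus:
        if rng.random() < _CONSENSUS_P:
            out.append(b)
        else:
            out.append(BASES[rng.integers(4)])
    return "".join(out)


def _make_intron(rng, length, gc):
    """Canonical intron: GT + consensus tail + interior + py-tract + CAG."""
    tail = _consensus_sample(rng, _DONOR_TAIL)
    tract = "".join(
        BASES[rng.choice(4, p=[0.15, 0.30, 0.07, 0.48])]
        for _ in range(_ACCEPTOR_TRACT_LEN)
    )
    box = _consensus_sample(rng, "C")
    interior = _rand_seq(rng, length - 2 - len(tail) - len(tract) - 3, gc)
    intron = "GT" + tail + interior + tract + box + "AG"
    assert len(intron) == length
    return intron


def _gene_plan(rng, cfg: SimConfig):
    """Exon/intron lengths plus the optional skipped-exon index."""
    lo, hi = cfg.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    elo, ehi = cfg.exon_len_range
    exon_lens = [int(rng.integers(elo, ehi + 1)) for _ in range(n_exons)]
    skip_idx = None
    if n_exons >= 3 and rng.random() < cfg.isoform_prob:
        skip_idx = int(rng.integers(1, n_exons - 1))
        # codon-align the skipped exon so the skip isoform stays stop-free
        exon_lens[skip_idx] -= exon_lens[skip_idx] % 3
        cum = sum(exon_lens[:skip_idx])
        exon_lens[skip_idx - 1] -= cum % 3
    total = sum(exon_lens)
    exon_lens[-1] -= total % 3
    if exon_lens[-1] < 3 or (skip_idx is not None and
                             (exon_lens[skip_idx] < 3 or
                              exon_lens[skip_idx - 1] < 3)):
        return _gene_plan(rng, cfg)  # degenerate adjustment; redraw
    ilo, ihi = cfg.intron_len_range
    intron_lens = [int(rng.integers(ilo, ihi + 1)) for _ in range(n_exons - 1)]
    return exon_lens, intron_lens, skip_idx


def _make_cds(rng, n_codons):
    codons = ["ATG"]
    idx = rng.choice(len(_SENSE_CODONS), size=n_codons - 2, p=_CODON_W)
    codons.extend(_SENSE_CODONS[i] for i in idx)
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def simulate_genome(config: SimConfig):
    """Generate a genome and its truth annotation.

    Returns ``(GenomeSequence, truth_features)`` where the truth is a list
    of GFF features (gene, mRNA, exon, CDS, intron) with Parent links.
    """
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content

    gene_parts = []  # (block string incl. 6 nt upstream context, local exon
    #                  coords per isoform (transcript orientation), strand)
    for _ in range(config.n_genes):
        exon_lens, intron_lens, skip_idx = _gene_plan(rng, config)
        cds = _make_cds(rng, sum(exon_lens) // 3)
        pieces = [_consensus_sample(rng, _KOZAK)]
        local_exons = []  # (start, end) within block, transcript orientation
        cursor = len(_KOZAK)
        cds_off = 0
        for i, elen in enumerate(exon_lens):
            pieces.append(cds[cds_off : cds_off + elen])
            local_exons.append((cursor + 1, cursor + elen))
            cursor += elen
            cds_off += elen
            if i < len(exon_lens) - 1:
                ilen = intron_lens[i]
                pieces.append(_make_intron(rng, ilen, gc))
                cursor += ilen
        block = "".join(pieces)
        isoforms = [list(local_exons)]
        if skip_idx is not None:
            isoforms.append(
                [e for i, e in enumerate(local_exons) if i != skip_idx]
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene_parts.append((block, isoforms, strand))

    total_blocks = sum(len(b) for b, _, _ in gene_parts)
    slack = config.genome_length - total_blocks \
        - (config.n_genes + 1) * _MIN_INTERGENIC_GAP
    if slack < 0:
        raise ValueError(
            f"{config.n_genes} genes do not fit in {config.genome_length} bp"
        )
    extra = rng.multinomial(slack, np.full(config.n_genes + 1,
                                           1.0 / (config.n_genes + 1)))
    gaps = [_MIN_INTERGENIC_GAP + int(x) for x in extra]

    seq_parts = []
    features = []
    pos = 0
    for gi, (block, isoforms, strand) in enumerate(gene_parts):
        seq_parts.append(_rand_seq(rng, gaps[gi], gc))
        pos += gaps[gi]
        if strand == "+":
            placed = block
        else:
            placed = block.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
        block_start = pos  # 0-based offset of block within genome
        seq_parts.append(placed)
        pos += len(block)

        gene_id = f"g{gi + 1}"
        tx_feats = []
        gene_lo, gene_hi = None, None
        for ti, local in enumerate(isoforms):
            tid = f"{gene_id}.t{ti + 1}"
            genomic = []
            for s, e in local:
                if strand == "+":
                    gs = block_start + s
                    ge = block_start + e
                else:
                    gs = block_start + len(block) - e + 1
                    ge = block_start + len(block) - s + 1
                genomic.append((gs, ge))
            genomic.sort()
            lo, hi = genomic[0][0], genomic[-1][1]
            gene_lo = lo if gene_lo is None else min(gene_lo, lo)
            gene_hi = hi if gene_hi is None else max(gene_hi, hi)
            tx_feats.append(
                GffFeature("chr1", "sim", "mRNA", lo, hi, None, strand, None,
                           {"ID": tid, "Parent": gene_id})
            )
            ordered = genomic if strand == "+" else list(reversed(genomic))
            carried = 0
            for xi, (gs, ge) in enumerate(ordered):
                tx_feats.append(
                    GffFeature("chr1", "sim", "exon", gs, ge, None, strand,
                               None, {"ID": f"{tid}.exon{xi + 1}",
                                      "Parent": tid})
                )
                tx_feats.append(
                    GffFeature("chr1", "sim", "CDS", gs, ge, None, strand,
                               (3 - carried) % 3,
                               {"ID": f"{tid}.cds{xi + 1}", "Parent": tid})
                )
                carried = (carried + ge - gs + 1) % 3
            for xi in range(len(genomic) - 1):
                ivs, ive = genomic[xi][1] + 1, genomic[xi + 1][0] - 1
                tx_feats.append(
                    GffFeature("chr1", "sim", "intron", ivs, ive, None,
                               strand, None,
                               {"ID": f"{tid}.intron{xi + 1}", "Parent": tid})
                )
        features.append(
            GffFeature("chr1", "sim", "gene", gene_lo, gene_hi, None, strand,
                       None, {"ID": gene_id})
        )
        features.extend(tx_feats)

    seq_parts.append(_rand_seq(rng, gaps[-1], gc))
    genome = GenomeSequence(id="chr1", seq="".join(seq_parts))
    return genome, features


def _transcript_records(truth):
    if truth and isinstance(truth[0], TranscriptRecord):
        return list(truth)
    return transcripts_from_features(truth)


def _spliced_seq(genome, record: TranscriptRecord) -> str:
    exons = record.exons if record.strand == "+" else list(reversed(record.exons))
    return "".join(genome.subseq(s, e, record.strand) for s, e in exons)


def simulate_ests(genome, truth, config: SimConfig):
    """Sample ESTs from mature transcripts as exact truth-block alignments.

    Returns a list of SplicedAlignment.  ESTs are contiguous windows of a
    (randomly chosen) isoform's spliced sequence; a configurable fraction is
    drawn inside a single exon (unspliced).  Identity is 1.0 at zero error
    rate, otherwise sampled near 1 - est_error_rate; coverage is the
    window/transcript length ratio.
    """
    rng = np.random.default_rng(config.seed + 1)
    records = _transcript_records(truth)
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for r in records:
        gene = r.transcript_id.rsplit(".", 1)[0]
        by_gene.setdefault(gene, []).append(r)

    alignments = []
    counter = 0
    for gene in sorted(by_gene):
        isoforms = by_gene[gene]
        n_est = int(rng.integers(config.est_per_gene_range[0],
                                 config.est_per_gene_range[1] + 1))
        for _ in range(n_est):
            r = isoforms[int(rng.integers(len(isoforms)))]
            tx_exons = r.exons if r.strand == "+" else list(reversed(r.exons))
            tlen = sum(e - s + 1 for s, e in r.exons)
            counter += 1
            est_id = f"est_{counter:05d}"
            if rng.random() < config.unspliced_fraction:
                # window inside one exon
                xi = int(rng.integers(len(tx_exons)))
                s, e = tx_exons[xi]
                elen = e - s + 1
                w = int(min(rng.integers(*_order(config.est_len_range)), elen))
                w = max(w, min(30, elen))
                off = int(rng.integers(0, elen - w + 1))
                blocks = [(s + off, s + off + w - 1)]
                cov = w / tlen
            else:
                w = int(min(rng.integers(*_order(config.est_len_range)), tlen))
                off = int(rng.integers(0, tlen - w + 1))
                blocks = _project_window(tx_exons, r.strand, off, w)
                cov = w / tlen
            if config.est_error_rate == 0.0:
                ident = 1.0
            else:
                ident = float(
                    np.clip(rng.normal(1.0 - config.est_error_rate,
                                       config.est_error_rate / 4.0), 0.0, 1.0)
                )
                ident = round(ident, 4)
            alignments.append(
                SplicedAlignment(est_id=est_id, seqid=r.seqid,
                                 strand=r.strand, blocks=blocks,
                                 identity=ident, coverage=round(cov, 4))
            )
    alignments.sort(key=lambda a: (a.seqid, a.span, a.est_id))
    return alignments


def _order(rng_range):
    lo, hi = rng_range
    return lo, hi + 1


def _project_window(tx_exons, strand, off, w):
    """Genomic blocks of transcript window [off, off+w-1] (0-based)."""
    blocks = []
    cum = 0
    a, b = off, off + w - 1
    for s, e in tx_exons:
        elen = e - s + 1
        lo = max(a, cum)
        hi = min(b, cum + elen - 1)
        if lo <= hi:
            if strand == "+":
                blocks.append((s + (lo - cum), s + (hi - cum)))
            else:
                blocks.append((e - (hi - cum), e - (lo - cum)))
        cum += elen
    blocks.sort()
    return blocks


def est_sequences(genome, alignments):
    """Spliced EST sequences (for users who want to run a real aligner)."""
    out = []
    for a in alignments:
        blocks = a.blocks if a.strand == "+" else list(reversed(a.blocks))
        seq = "".join(genome.subseq(s, e, a.strand) for s, e in blocks)
        out.append(GenomeSequence(id=a.est_id, seq=seq))
    return out


def sample_intron_lengths(config: SimConfig, n: int, seed: int | None = None):
    """Intron lengths as the genome simulator draws them (uniform range)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.intron_len_range
    return rng.integers(lo, hi + 1, size=n).tolist()


def _signal_window(genome, pos, strand, kind):
    offset, width, _ = SIGNAL_GEOMETRY[kind]
    L = genome.length
    if strand == "-":
        seq = genome.revcomp
        p = L - pos + 1
    else:
        seq = genome.seq
        p = pos
    lo = p - offset
    hi = lo + width - 1
    if lo < 1 or hi > L:
        return None
    w = seq[lo - 1 : hi]
    return None if "N" in w else w


def train_from_truth(genome, truth, order: int = 4, pseudocount: float = 0.5,
                     min_introns: int = 20) -> ModelParams:
    """Train PWMs and the coding model from a truth annotation.

    Splice windows come from annotated introns, start windows from
    transcript 5' ends, the coding chain from spliced CDS sequences and the
    background chain from intergenic sequence.  Gene-model intron bounds are
    set from the observed intron lengths.
    """
    records = _transcript_records(truth)
    introns = sorted({(t.seqid, t.strand, s, e)
                      for t in records for (s, e) in t.introns})
    if len(introns) < min_introns:
        raise ValueError(
            f"need >= {min_introns} annotated introns to train, "
            f"got {len(introns)}"
        )

    donor_windows, acceptor_windows = [], []
    for _, strand, s, e in introns:
        dpos = s if strand == "+" else e
        apos = e - 1 if strand == "+" else s + 1
        w = _signal_window(genome, dpos, strand, "donor")
        if w:
            donor_windows.append(w)
        w = _signal_window(genome, apos, strand, "acceptor")
        if w:
            acceptor_windows.append(w)
    start_windows = []
    for t in records:
        pos = t.exons[0][0] if t.strand == "+" else t.exons[-1][1]
        w = _signal_window(genome, pos, t.strand, "start")
        if w:
            start_windows.append(w)

    # intergenic background: complement of transcript spans
    spans = sorted(t.span for t in records)
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    noncoding = []
    cur = 1
    for s, e in merged:
        if s > cur:
            noncoding.append(genome.seq[cur - 1 : s - 1])
        cur = e + 1
    if cur <= genome.length:
        noncoding.append(genome.seq[cur - 1 :])
    noncoding = [s for s in noncoding if len(s) > order]

    cds_seqs = [_spliced_seq(genome, t) for t in records]
    cds_seqs = [s for s in cds_seqs if len(s) % 3 == 0 and "N" not in s]

    all_bg = "".join(noncoding)
    counts = {b: max(all_bg.count(b), 1) for b in "ACGT"}
    tot = sum(counts.values())
    background = {b: counts[b] / tot for b in "ACGT"}

    pwms = {
        "donor": train_pwm(donor_windows, "donor", background, pseudocount),
        "acceptor": train_pwm(acceptor_windows, "acceptor", background,
                              pseudocount),
        "start": train_pwm(start_windows, "start", background, pseudocount),
    }
    coding = train_coding_model(cds_seqs, noncoding, order=order,
                                pseudocount=pseudocount)

    # self-calibrated signal thresholds: keep every training site with a
    # safety margin for held-out variation
    from .signal_content import score_pwm

    thresholds = {}
    site_lists = {
        "donor": [(s if st == "+" else e, st) for _, st, s, e in introns],
        "acceptor": [(e - 1 if st == "+" else s + 1, st)
                     for _, st, s, e in introns],
        "start": [
            (t.exons[0][0] if t.strand == "+" else t.exons[-1][1], t.strand)
            for t in records
        ],
    }
    for kind, sites in site_lists.items():
        scores = [score_pwm(pwms[kind], genome, pos, st) for pos, st in sites]
        scores = [s for s in scores if s is not None]
        thresholds[kind] = (min(scores) - 5.0) if scores else 0.0

    # intron length bounds learned from the annotation, with margins
    ilens = [e - s + 1 for _, _, s, e in introns]
    rules = GeneModelRules(
        min_intron_len=max(4, int(0.8 * min(ilens))),
        max_intron_len=max(int(1.25 * max(ilens)) + 10, min(ilens) + 20),
        min_intergenic=100,
    )
    return ModelParams(pwms=pwms, coding=coding, gene_model=rules,
                       signal_thresholds=thresholds)
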