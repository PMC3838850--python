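"""Multi-level accuracy evaluation of gene predictions against an annotation.

Two comparison modes are provided.  In gene-projection mode, transcripts on
each side are clustered into genes by same-strand exon overlap, each gene is
projected to the genome (union of its exon intervals), and sensitivity (SN),
specificity (SP), their mean (SS), wrong (W) and missing (M) fractions are
computed at the nucleotide, exon, intron, gene and transcript levels.  In
best-transcript-pair (BTP) mode the same measures are computed after
restricting both sides to a one-to-one (plus split/join one-to-many)
transcript pairing by shared coding-base overlap.

SP is computed as TP/(TP+FP) at every level: a true-negative count is
undefined for exon- or transcript-shaped features, and the TP-based form is
the standard one for gene-prediction accuracy.  Ratios with a zero
denominator are reported as 0 and flagged degenerate, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import TranscriptRecord

__all__ = [
    "AccuracyReport",
    "BtpPairing",
    "cluster_into_genes",
    "project_gene",
    "evaluate",
    "btp_map",
    "titration_experiment",
    "report_table",
]

LEVELS = ("nucleotide", "exon", "intron", "gene", "transcript")


@dataclass
class AccuracyReport:
    level: str
    mode: str
    tp: int
    fp: int
    fn: int
    sn: float
    sp: float
    ss: float
    w: float
    m: float
    degenerate: bool = False
    # gene level only: matched counts are asymmetric under overlap matching
    pred_matched: int | None = None


def _ratio(num, den):
    if den == 0:
        return 0.0, True
    return num / den, False


def _make_report(level, mode, tp, fp, fn, w, m, pred_matched=None):
    sn, d1 = _ratio(tp, tp + fn)
    if level == "gene" and pred_matched is not None:
        sp, d2 = _ratio(pred_matched, pred_matched + fp)
    else:
        sp, d2 = _ratio(tp, tp + fp)
    return AccuracyReport(level=level, mode=mode, tp=tp, fp=fp, fn=fn,
                          sn=sn, sp=sp, ss=(sn + sp) / 2.0, w=w, m=m,
                          degenerate=d1 or d2, pred_matched=pred_matched)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def cluster_into_genes(transcripts: list[TranscriptRecord]):
    """Connected components under same-strand exon overlap (>= 1 bp)."""
    ts = sorted(transcripts, key=lambda t: (t.seqid, t.strand, t.span,
                                            t.transcript_id))
    n = len(ts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    # sweep by (seqid, strand); exon-overlap check within span-overlapping pairs
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ts[i], ts[j]
            if (a.seqid, a.strand) != (b.seqid, b.strand):
                continue
            if b.span[0] > a.span[1]:
                break
            if any(_overlaps(xa, xb) for xa in a.exons for xb in b.exons):
                union(i, j)

    comp: dict[int, list[TranscriptRecord]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(ts[i])
    return [comp[r] for r in sorted(comp)]


def project_gene(gene_cluster: list[TranscriptRecord]):
    """Merged union of all exon intervals of a gene cluster."""
    ivs = sorted(iv for t in gene_cluster for iv in t.exons)
    merged = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _interval_total(ivs):
    return sum(e - s + 1 for s, e in ivs)


def _interval_intersection(a, b):
    """Total overlapping bases between two sorted disjoint interval lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            total += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _zero_overlap_fraction(feats_a, feats_b):
    """Fraction of features in a with zero overlap to any feature in b
    (same seqid and strand)."""
    if not feats_a:
        return 0.0
    by_key: dict[tuple, list] = {}
    for (seqid, strand, s, e) in feats_b:
        by_key.setdefault((seqid, strand), []).append((s, e))
    for k in by_key:
        by_key[k].sort()
    wrong = 0
    for (seqid, strand, s, e) in feats_a:
        ivs = by_key.get((seqid, strand), [])
        if not any(_overlaps((s, e), iv) for iv in ivs):
            wrong += 1
    return wrong / len(feats_a)


def _projected_exons(gene_clusters):
    """Set of (seqid, strand, start, end) projected exon intervals."""
    out = set()
    for cluster in gene_clusters:
        seqid, strand = cluster[0].seqid, cluster[0].strand
        for s, e in project_gene(cluster):
            out.add((seqid, strand, s, e))
    return out


def _distinct_introns(transcripts):
    return {
        (t.seqid, t.strand, s, e) for t in transcripts for (s, e) in t.introns
    }


def _coverage_by_strand(gene_clusters):
    """(seqid, strand) -> sorted disjoint projected intervals."""
    cov: dict[tuple, list] = {}
    for cluster in gene_clusters:
        key = (cluster[0].seqid, cluster[0].strand)
        cov.setdefault(key, []).extend(project_gene(cluster))
    for key in cov:
        ivs = sorted(cov[key])
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        cov[key] = merged
    return cov


def _evaluate_sets(pred, annot, mode):
    """Core level-by-level comparison of two transcript sets."""
    reports = {}
    pred_genes = cluster_into_genes(pred)
    annot_genes = cluster_into_genes(annot)

    # nucleotide
    pcov = _coverage_by_strand(pred_genes)
    acov = _coverage_by_strand(annot_genes)
    tp = sum(
        _interval_intersection(pcov[k], acov[k]) for k in pcov if k in acov
    )
    pbases = sum(_interval_total(v) for v in pcov.values())
    abases = sum(_interval_total(v) for v in acov.values())
    fp, fn = pbases - tp, abases - tp
    sp = _ratio(tp, pbases)[0]
    sn = _ratio(tp, abases)[0]
    reports["nucleotide"] = _make_report("nucleotide", mode, tp, fp, fn,
                                         1.0 - sp if pbases else 0.0,
                                         1.0 - sn if abases else 0.0)

    # exon (projected, exact boundaries)
    pex = _projected_exons(pred_genes)
    aex = _projected_exons(annot_genes)
    tp = len(pex & aex)
    reports["exon"] = _make_report(
        "exon", mode, tp, len(pex) - tp, len(aex) - tp,
        _zero_overlap_fraction(pex, aex), _zero_overlap_fraction(aex, pex),
    )

    # intron (distinct, exact boundaries)
    pin = _distinct_introns(pred)
    ain = _distinct_introns(annot)
    tp = len(pin & ain)
    reports["intron"] = _make_report(
        "intron", mode, tp, len(pin) - tp, len(ain) - tp,
        _zero_overlap_fraction(pin, ain), _zero_overlap_fraction(ain, pin),
    )

    # gene: found iff same-strand exonic overlap >= 1 bp
    def gene_hits(genes_a, cov_b):
        hit = 0
        for cluster in genes_a:
            key = (cluster[0].seqid, cluster[0].strand)
            proj = project_gene(cluster)
            if key in cov_b and _interval_intersection(proj, cov_b[key]) > 0:
                hit += 1
        return hit

    annot_found = gene_hits(annot_genes, pcov)
    pred_found = gene_hits(pred_genes, acov)
    reports["gene"] = _make_report(
        "gene", mode, annot_found,
        len(pred_genes) - pred_found, len(annot_genes) - annot_found,
        (len(pred_genes) - pred_found) / len(pred_genes) if pred_genes else 0.0,
        (len(annot_genes) - annot_found) / len(annot_genes) if annot_genes else 0.0,
        pred_matched=pred_found,
    )

    # transcript: exact structure match (complete intron chain + CDS bounds)
    pstruct = {t.structure for t in pred}
    astruct = {t.structure for t in annot}
    tp = len(pstruct & astruct)
    pfeat = {(s[0], s[1], s[2][0][0], s[2][-1][1]) for s in pstruct}
    afeat = {(s[0], s[1], s[2][0][0], s[2][-1][1]) for s in astruct}
    reports["transcript"] = _make_report(
        "transcript", mode, tp, len(pstruct) - tp, len(astruct) - tp,
        _zero_overlap_fraction(pfeat, afeat), _zero_overlap_fraction(afeat, pfeat),
    )
    return reports


@dataclass
class BtpPairing:
    pairs: list[tuple[TranscriptRecord, TranscriptRecord, int]]
    unmatched_pred: list[TranscriptRecord] = field(default_factory=list)
    unmatched_annot: list[TranscriptRecord] = field(default_factory=list)


def btp_map(pred: list[TranscriptRecord], annot: list[TranscriptRecord],
            split_join_fraction: float = 0.5) -> BtpPairing:
    """Best-transcript-pair mapping by shared coding-base overlap.

    Greedy maximum-weight one-to-one matching first; afterwards an unmatched
    transcript may attach to an already-matched partner on the other side
    (split/join case) when their overlap exceeds ``split_join_fraction`` of
    the unmatched transcript's coding length.
    """
    weights = []
    for i, p in enumerate(pred):
        for j, a in enumerate(annot):
            if (p.seqid, p.strand) != (a.seqid, a.strand):
                continue
            ov = _interval_intersection(sorted(p.exons), sorted(a.exons))
            if ov > 0:
                weights.append((ov, i, j))
    weights.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_a: set[int] = set()
    pairs = []
    for ov, i, j in weights:
        if i in used_p or j in used_a:
            continue
        used_p.add(i)
        used_a.add(j)
        pairs.append((pred[i], annot[j], ov))
    # split/join attachments
    for ov, i, j in weights:
        if i in used_p and j in used_a:
            continue
        if i not in used_p and j in used_a:
            plen = _interval_total(pred[i].exons)
            if ov > split_join_fraction * plen:
                pairs.append((pred[i], annot[j], ov))
                used_p.add(i)
        elif j not in used_a and i in used_p:
            alen = _interval_total(annot[j].exons)
            if ov > split_join_fraction * alen:
                pairs.append((pred[i], annot[j], ov))
                used_a.add(j)
    return BtpPairing(
        pairs=pairs,
        unmatched_pred=[p for i, p in enumerate(pred) if i not in used_p],
        unmatched_annot=[a for j, a in enumerate(annot) if j not in used_a],
    )


def evaluate(pred, annot, mode: str = "gene_projection"):
    """Accuracy reports per level; ``mode`` is gene_projection or BTP."""
    pred = list(pred)
    annot = list(annot)
    for t in pred + annot:
        if t.strand not in ("+", "-"):
            raise ValueError(f"transcript {t.transcript_id}: undefined strand")
    if mode in ("gene_projection", "gene"):
        return _evaluate_sets(pred, annot, "gene_projection")
    if mode.lower() == "btp":
        pairing = btp_map(pred, annot)
        bp = [p for p, _, _ in pairing.pairs]
        ba = [a for _, a, _ in pairing.pairs]
        # deduplicate while preserving order (split/join repeats partners)
        bp = list({id(t): t for t in bp}.values())
        ba = list({id(t): t for t in ba}.values())
        return _evaluate_sets(bp, ba, "BTP")
    raise ValueError(f"unknown evaluation mode: {mode}")


def report_table(reports: dict) -> pd.DataFrame:
    rows = []
    for level in LEVELS:
        r = reports[level]
        rows.append(
            {
                "level": level, "mode": r.mode, "TP": r.tp, "FP": r.fp,
                "FN": r.fn, "SN": r.sn, "SP": r.sp, "SS": r.ss,
                "W": r.w, "M": r.m, "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def titration_experiment(genome, truth_transcripts, alignments, fractions,
                         n_reps: int, seed: int, params=None,
                         cluster_config=None, intron_bonus=None):
    """Accuracy as a function of the fraction of evidence introns supplied.

    The full pipeline (filter, cluster, infer introns, enumerate candidates)
    runs once; then for each fraction and replicate a seeded random subset
    of the inferred introns is given to the assembler and the predictions
    are evaluated against the truth.  Returns a tidy DataFrame with mean-SS
    columns at the gene, exon and nucleotide levels.
    """
    from .chainer import assemble
    from .est_evidence import ClusterConfig, cluster_alignments, \
        filter_alignments, infer_introns
    from .exon_builder import build_candidates
    from .formats_io import TranscriptRecord
    from .synthetic import train_from_truth

    if params is None:
        params = train_from_truth(genome, truth_transcripts)
    if cluster_config is None:
        cluster_config = ClusterConfig()
    if intron_bonus is None:
        intron_bonus = params.intron_bonus

    kept, _ = filter_alignments(alignments, cluster_config)
    clusters = cluster_alignments(kept, cluster_config)
    introns = []
    for cl in clusters:
        introns.extend(infer_introns(cl, genome, cluster_config,
                                     pwms=params.pwms))
    from .chainer import JoinIndex, validate_evidence
    introns, _ = validate_evidence(introns, genome, params.gene_model)
    candidates = build_candidates(genome, params)
    join_index = JoinIndex(candidates, params.gene_model)

    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(fractions) * n_reps)
    for fi, f in enumerate(fractions):
        for rep in range(n_reps):
            rng = np.random.default_rng(children[fi * n_reps + rep])
            k = int(round(f * len(introns)))
            idx = sorted(rng.choice(len(introns), size=k, replace=False)) \
                if 0 < k < len(introns) else (
                    list(range(len(introns))) if k >= len(introns) else []
                )
            subset = [introns[i] for i in idx]
            preds = assemble(candidates, subset, params.gene_model,
                             intron_bonus, join_index=join_index)
            pred_records = [
                TranscriptRecord(t.transcript_id, t.seqid, t.strand,
                                 t.exon_intervals)
                for g in preds for t in g.transcripts
            ]
            reports = evaluate(pred_records, truth_transcripts)
            rows.append(
                {
                    "fraction": f, "rep": rep, "n_introns": len(subset),
                    "ss_gene": reports["gene"].ss,
                    "ss_exon": reports["exon"].ss,
                    "ss_nucleotide": reports["nucleotide"].ss,
                }
            )
    return pd.DataFrame(rows)
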