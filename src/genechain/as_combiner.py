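"""Two procedures for adding alternative isoforms to the predictions.

AS1 keeps every EST-derived transcript and adds only the ab initio/evidence
predictions that do not exon-overlap any of them on the same strand: fully
EST-covered loci get their (possibly multi-isoform) EST transcripts, the
rest of the genome gets the single-transcript predictions.

AS2 runs the assembler once per "bin" of mutually overlapping EST-derived
CDSs: each locus contributes one CDS per bin (cyclically re-used so every
bin covers every locus), injected as boosted exon candidates together with
the unassociated evidence introns; the per-bin predictions are pooled and
exact duplicate structures removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chainer import assemble, inject_cds_evidence
from .evaluator import cluster_into_genes
from .formats_io import TranscriptRecord

__all__ = [
    "LocusBinAssignment",
    "as1_combine",
    "as2_bin",
    "as2_run",
    "DEFAULT_CDS_BOOST",
]

DEFAULT_CDS_BOOST = 100.0


def _exon_overlap(a: TranscriptRecord, b: TranscriptRecord) -> bool:
    if (a.seqid, a.strand) != (b.seqid, b.strand):
        return False
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if s1 <= e2 and s2 <= e1:
                return True
    return False


def as1_combine(est_transcripts, ag_genes):
    """EST transcripts plus the predictions that do not overlap them.

    Overlap is same-strand exonic overlap of >= 1 bp.  Sources are tagged
    "est" and "AG" respectively.
    """
    out = []
    for t in est_transcripts:
        out.append(TranscriptRecord(t.transcript_id, t.seqid, t.strand,
                                    list(t.exons), source="est"))
    for g in ag_genes:
        if any(_exon_overlap(g, t) for t in est_transcripts):
            continue
        out.append(TranscriptRecord(g.transcript_id, g.seqid, g.strand,
                                    list(g.exons), source="AG"))
    out.sort(key=lambda t: (t.seqid, t.span, t.transcript_id))
    return out


@dataclass
class LocusBinAssignment:
    n_bins: int
    bins: list[list[TranscriptRecord]]
    assignment: dict[str, tuple[int, ...]] = field(default_factory=dict)


def as2_bin(cds_by_locus) -> LocusBinAssignment:
    """Distribute overlapping CDSs into bins; re-use CDSs to fill empty bins.

    ``cds_by_locus`` is either a list of loci (lists of CDS transcripts) or
    a flat list, in which case loci are formed by same-strand exon overlap.
    The bin count equals the largest per-locus transcript count; within a
    locus CDSs are ordered longest-first and bin i takes CDS ``i mod k``.
    """
    if cds_by_locus and isinstance(cds_by_locus[0], TranscriptRecord):
        loci = cluster_into_genes(cds_by_locus)
    else:
        loci = [list(l) for l in cds_by_locus]
    loci = [l for l in loci if l]
    if not loci:
        return LocusBinAssignment(n_bins=0, bins=[])
    n_bins = max(len(l) for l in loci)
    bins: list[list[TranscriptRecord]] = [[] for _ in range(n_bins)]
    assignment: dict[str, list[int]] = {}
    for locus in loci:
        ordered = sorted(
            locus,
            key=lambda t: (-(t.span[1] - t.span[0] + 1), t.span[0],
                           t.transcript_id),
        )
        k = len(ordered)
        for b in range(n_bins):
            cds = ordered[b % k]
            bins[b].append(cds)
            assignment.setdefault(cds.transcript_id, []).append(b)
    return LocusBinAssignment(
        n_bins=n_bins, bins=bins,
        assignment={k: tuple(v) for k, v in assignment.items()},
    )


def _unassociated(evidence_introns, cds_transcripts):
    """Evidence introns not contained in any CDS transcript span."""
    spans = [
        (t.seqid, t.strand, t.span[0], t.span[1]) for t in cds_transcripts
    ]
    out = []
    for it in evidence_introns:
        contained = any(
            it.seqid == sq and it.strand == st and s <= it.start
            and it.end <= e
            for sq, st, s, e in spans
        )
        if not contained:
            out.append(it)
    return out


def as2_run(bins, candidates, evidence_introns, rules,
            intron_bonus=None, boost: float = DEFAULT_CDS_BOOST,
            model=None, genome=None):
    """Assemble once per bin with that bin's CDS evidence injected.

    ``bins`` is a LocusBinAssignment or a plain list of CDS lists.  Returns
    the pooled transcripts with exact duplicate exon structures removed,
    tagged source "AS2".
    """
    from .chainer import DEFAULT_INTRON_BONUS

    if intron_bonus is None:
        intron_bonus = DEFAULT_INTRON_BONUS
    bin_lists = bins.bins if isinstance(bins, LocusBinAssignment) else bins
    all_cds = [t for b in bin_lists for t in b]
    shared = _unassociated(evidence_introns, all_cds)

    seen: set[tuple] = set()
    out = []
    for bi, bin_cds in enumerate(bin_lists):
        aug, cds_ev, _rejected = inject_cds_evidence(
            bin_cds, candidates, boost, model=model, genome=genome
        )
        merged_ev = {e.key: e for e in shared}
        for e in cds_ev:
            merged_ev.setdefault(e.key, e)
        preds = assemble(aug, list(merged_ev.values()), rules, intron_bonus)
        for g in preds:
            for t in g.transcripts:
                rec = TranscriptRecord(
                    f"bin{bi}.{t.transcript_id}", t.seqid, t.strand,
                    t.exon_intervals, source="AS2",
                )
                if rec.structure in seen:
                    continue
                seen.add(rec.structure)
                out.append(rec)
    out.sort(key=lambda t: (t.seqid, t.span, tuple(t.exons)))
    return out
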