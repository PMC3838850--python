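"""Stage orchestration: one entry point that wires the pipeline end to end.

Stages: filter alignments -> cluster -> infer evidence introns
(-> EST transcripts and ORFs in the AS modes) -> enumerate and chain exons
(-> AS1/AS2 combination) -> optional evaluation.  Every stage's artifact is
written to the output directory as GFF3 so stages stay independently
inspectable, and the run log records per-stage counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .as_combiner import as1_combine, as2_bin, as2_run
from .chainer import assemble, validate_evidence
from .est_evidence import (
    ClusterConfig,
    assemble_est_transcripts,
    cluster_alignments,
    extract_cds,
    filter_alignments,
    infer_introns,
)
from .evaluator import evaluate, report_table
from .exon_builder import build_candidates
from .formats_io import (
    GffFeature,
    TranscriptRecord,
    features_from_transcripts,
    write_gff3,
)

log = logging.getLogger("genechain")

MODES = ("introns_only", "AS1", "AS2")


@dataclass
class PipelineRun:
    mode: str = "introns_only"
    outdir: str | Path = "."
    cluster_config: ClusterConfig = field(default_factory=ClusterConfig)
    intron_bonus: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _intron_features(introns):
    return [
        GffFeature(i.seqid, "genechain", "intron", i.start, i.end, None,
                   i.strand, None,
                   {"ID": f"intron_{k + 1:05d}", "support": str(i.support),
                    "source_tag": i.source})
        for k, i in enumerate(introns)
    ]


def predictions_to_records(preds):
    return [
        TranscriptRecord(t.transcript_id, t.seqid, t.strand,
                         t.exon_intervals, source="AG")
        for g in preds for t in g.transcripts
    ]


def run(run_config: PipelineRun, genome, alignments, params,
        annotation=None):
    """Execute the configured pipeline; returns a dict of stage artifacts.

    ``genome`` is a GenomeSequence, ``alignments`` a list of
    SplicedAlignment, ``params`` a trained ModelParams.  ``annotation``
    (TranscriptRecords), when given, triggers evaluation of the final set.
    """
    outdir = Path(run_config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cc = run_config.cluster_config
    bonus = (params.intron_bonus if run_config.intron_bonus is None
             else run_config.intron_bonus)
    art: dict = {}

    kept, discarded = filter_alignments(alignments, cc)
    log.info("filter: kept %d / %d alignments", len(kept), len(alignments))
    clusters = cluster_alignments(kept, cc)
    log.info("cluster: %d clusters", len(clusters))

    introns = []
    est_transcripts = []
    for cl in clusters:
        cl_introns = infer_introns(cl, genome, cc, pwms=params.pwms)
        introns.extend(cl_introns)
        if run_config.mode in ("AS1", "AS2"):
            est_transcripts.extend(assemble_est_transcripts(cl, cl_introns))
    introns, rejected = validate_evidence(introns, genome, params.gene_model)
    log.info("introns: %d accepted, %d rejected", len(introns), len(rejected))
    write_gff3(_intron_features(introns), outdir / "evidence_introns.gff3")

    candidates = build_candidates(genome, params)
    log.info("candidates: %d exon candidates", len(candidates))

    preds = assemble(candidates, introns, params.gene_model, bonus)
    ag_records = predictions_to_records(preds)
    log.info("predict: %d genes", len(preds))
    ev_attrs = {
        t.transcript_id: {"evidence_introns": str(t.evidence_intron_count)}
        for g in preds for t in g.transcripts
    }
    write_gff3(
        features_from_transcripts(ag_records, extra_mrna_attrs=ev_attrs),
        outdir / "predictions.gff3",
    )

    final = ag_records
    if run_config.mode in ("AS1", "AS2"):
        est_records = [t.to_record() for t in est_transcripts]
        write_gff3(features_from_transcripts(est_records),
                   outdir / "est_transcripts.gff3")
        cds = [c for c in (extract_cds(genome, t) for t in est_transcripts)
               if c is not None]
        log.info("orfs: %d CDS transcripts", len(cds))
        if run_config.mode == "AS1":
            final = as1_combine(est_records, ag_records)
        else:
            bins = as2_bin(cds)
            log.info("as2: %d bins", bins.n_bins)
            final = as2_run(bins, candidates, introns, params.gene_model,
                            intron_bonus=bonus, model=params.coding,
                            genome=genome)
        write_gff3(features_from_transcripts(final),
                   outdir / f"final_{run_config.mode.lower()}.gff3")

    art.update(
        alignments_kept=kept, clusters=clusters, evidence_introns=introns,
        candidates=candidates, predictions=preds, final=final,
        est_transcripts=est_transcripts,
    )
    art["counts"] = {
        "alignments_in": len(alignments),
        "alignments_kept": len(kept),
        "clusters": len(clusters),
        "introns_accepted": len(introns),
        "candidates": len(candidates),
        "genes": len(preds),
        "final_transcripts": len(final),
    }
    if annotation is not None:
        reports = evaluate(final, annotation)
        art["reports"] = reports
        table = report_table(reports)
        table.to_csv(outdir / "accuracy.tsv", sep="\t", index=False)
        log.info("evaluate:\n%s", table.to_string(index=False))
    return art
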