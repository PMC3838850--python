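"""Readers and writers for the formats the pipeline touches.

This module is the single home for coordinate conventions: every coordinate
anywhere in the toolkit is 1-based inclusive on the forward strand of the
genome.  Features on the reverse strand store forward coordinates with
``strand == "-"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from gffutils.feature import feature_from_line

__all__ = [
    "FormatError",
    "GenomeSequence",
    "GffFeature",
    "SplicedAlignment",
    "TranscriptRecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_spliced_alignments",
    "transcripts_from_features",
    "features_from_transcripts",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N}, uppercase."""

    id: str
    seq: str
    _revcomp: str | None = field(default=None, repr=False, compare=False)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def revcomp(self) -> str:
        """Reverse complement of the full sequence (cached)."""
        if self._revcomp is None:
            self._revcomp = self.seq.translate(_COMPLEMENT)[::-1]
        return self._revcomp

    def subseq(self, start: int, end: int, strand: str = "+") -> str:
        """1-based inclusive slice; for ``strand == '-'`` the reverse complement."""
        if start < 1 or end > self.length or start > end:
            raise ValueError(
                f"subseq({start},{end}) out of bounds for {self.id} (len {self.length})"
            )
        s = self.seq[start - 1 : end]
        if strand == "-":
            return s.translate(_COMPLEMENT)[::-1]
        return s


@dataclass
class GffFeature:
    """One GFF3 line; coordinates 1-based inclusive."""

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None
    strand: str
    phase: int | None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"feature {self.type} {self.seqid}:{self.start}-{self.end}: start > end"
            )
        if self.start < 1:
            raise FormatError(f"feature start {self.start} < 1")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"unknown strand symbol {self.strand!r}")


@dataclass
class SplicedAlignment:
    """An EST/mRNA-to-genome alignment as ordered, non-overlapping blocks.

    Gaps between consecutive blocks are candidate introns.
    """

    est_id: str
    seqid: str
    strand: str
    blocks: list[tuple[int, int]]
    identity: float
    coverage: float

    def __post_init__(self):
        self.blocks = sorted(tuple(b) for b in self.blocks)
        prev_end = 0
        for s, e in self.blocks:
            if s <= prev_end:
                raise FormatError(
                    f"alignment {self.est_id}: blocks overlap or touch at {s}"
                )
            if s > e:
                raise FormatError(f"alignment {self.est_id}: block start > end")
            prev_end = e
        for name, v in (("identity", self.identity), ("coverage", self.coverage)):
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"alignment {self.est_id}: {name}={v} outside [0,1]")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Block gaps as (first intronic base, last intronic base)."""
        return [
            (self.blocks[i][1] + 1, self.blocks[i + 1][0] - 1)
            for i in range(len(self.blocks) - 1)
        ]

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class TranscriptRecord:
    """A minimal transcript: ordered coding exon intervals on one strand.

    Shared currency between the predictor, the EST module, the isoform
    combiners and the evaluator.
    """

    transcript_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    source: str = ""

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def structure(self) -> tuple:
        """Hashable exact-structure key (seqid, strand, exon chain)."""
        return (self.seqid, self.strand, tuple(self.exons))


def read_fasta(path) -> list[GenomeSequence]:
    """Read a multi-record FASTA; uppercase, non-ACGTN mapped to N."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(f"{path}: line {lineno}: expected FASTA header")
                break
        else:
            raise FormatError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        records.append(GenomeSequence(id=rec.id, seq=seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _parse_gff_line(line: str, lineno: int, path) -> GffFeature:
    try:
        f = feature_from_line(line)
    except Exception as exc:  # gffutils raises several types
        raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    score = None if f.score in (".", "", None) else float(f.score)
    phase = None if f.frame in (".", "", None) else int(f.frame)
    attrs = {k: v[0] if isinstance(v, list) else v for k, v in f.attributes.items()}
    try:
        return GffFeature(
            seqid=f.seqid,
            source=f.source,
            type=f.featuretype,
            start=int(f.start),
            end=int(f.end),
            score=score,
            strand=f.strand if f.strand else ".",
            phase=phase,
            attributes=attrs,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: line {lineno}: {exc}") from exc


def read_gff3(path, feature_filter: set[str] | None = None) -> list[GffFeature]:
    """Read GFF3 features, optionally restricted to a set of feature types."""
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns"
                )
            feat = _parse_gff_line(line, lineno, path)
            if feature_filter is None or feat.type in feature_filter:
                feats.append(feat)
    return feats


def _fmt_attrs(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_gff3(features: list[GffFeature], path) -> None:
    """Write features sorted by (seqid, start, end); emits the version header."""
    feats = sorted(features, key=lambda f: (f.seqid, f.start, f.end, f.type))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            score = "." if f.score is None else f"{f.score:.6g}"
            phase = "." if f.phase is None else str(f.phase)
            fh.write(
                "\t".join(
                    [
                        f.seqid,
                        f.source,
                        f.type,
                        str(f.start),
                        str(f.end),
                        score,
                        f.strand,
                        phase,
                        _fmt_attrs(f.attributes),
                    ]
                )
                + "\n"
            )


def read_spliced_alignments(path) -> list[SplicedAlignment]:
    """Read a GFF3 match_part dialect: one alignment = blocks sharing an ID.

    Each line must carry ``identity`` and ``coverage`` attributes, identical
    across the blocks of one ID.
    """
    feats = read_gff3(path, feature_filter={"match_part"})
    by_id: dict[str, list[GffFeature]] = {}
    for f in feats:
        aln_id = f.attributes.get("ID")
        if aln_id is None:
            raise FormatError(f"{path}: match_part without ID attribute")
        by_id.setdefault(aln_id, []).append(f)
    alignments = []
    for aln_id, parts in by_id.items():
        seqids = {p.seqid for p in parts}
        strands = {p.strand for p in parts}
        if len(seqids) > 1:
            raise FormatError(f"alignment {aln_id}: blocks on mixed seqids {seqids}")
        if len(strands) > 1:
            raise FormatError(f"alignment {aln_id}: blocks on mixed strands {strands}")
        idents = {p.attributes.get("identity") for p in parts}
        covs = {p.attributes.get("coverage") for p in parts}
        if len(idents) > 1 or len(covs) > 1:
            raise FormatError(f"alignment {aln_id}: identity/coverage disagree")
        ident, cov = idents.pop(), covs.pop()
        if ident is None or cov is None:
            raise FormatError(f"alignment {aln_id}: missing identity/coverage")
        alignments.append(
            SplicedAlignment(
                est_id=aln_id,
                seqid=parts[0].seqid,
                strand=strands.pop(),
                blocks=[(p.start, p.end) for p in parts],
                identity=float(ident),
                coverage=float(cov),
            )
        )
    alignments.sort(key=lambda a: (a.seqid, a.span, a.est_id))
    return alignments


def features_from_alignments(alignments: list[SplicedAlignment],
                             source: str = "genechain") -> list[GffFeature]:
    feats = []
    for a in alignments:
        for s, e in a.blocks:
            feats.append(
                GffFeature(
                    seqid=a.seqid, source=source, type="match_part",
                    start=s, end=e, score=None, strand=a.strand, phase=None,
                    attributes={
                        "ID": a.est_id,
                        "identity": f"{a.identity:.6g}",
                        "coverage": f"{a.coverage:.6g}",
                    },
                )
            )
    return feats


def transcripts_from_features(features: list[GffFeature]) -> list[TranscriptRecord]:
    """Build TranscriptRecords from GFF3 mRNA/exon features linked by Parent.

    Exon (or CDS, if a transcript has no exon lines) features are grouped by
    their Parent attribute; bare exon features without a Parent are ignored.
    """
    exons: dict[str, list[GffFeature]] = {}
    cds: dict[str, list[GffFeature]] = {}
    mrna_meta: dict[str, GffFeature] = {}
    for f in features:
        if f.type in ("mRNA", "transcript"):
            tid = f.attributes.get("ID")
            if tid:
                mrna_meta[tid] = f
        elif f.type in ("exon", "CDS"):
            parent = f.attributes.get("Parent")
            if parent:
                (exons if f.type == "exon" else cds).setdefault(parent, []).append(f)
    records = []
    for tid in sorted(set(exons) | set(cds) | set(mrna_meta)):
        parts = exons.get(tid) or cds.get(tid)
        if not parts:
            continue
        strands = {p.strand for p in parts}
        if len(strands) > 1:
            raise FormatError(f"transcript {tid}: exons on mixed strands")
        meta = mrna_meta.get(tid)
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                seqid=parts[0].seqid,
                strand=strands.pop(),
                exons=[(p.start, p.end) for p in parts],
                source=(meta.attributes.get("source_tag", "") if meta else ""),
            )
        )
    records.sort(key=lambda t: (t.seqid, t.span, t.transcript_id))
    return records


def features_from_transcripts(transcripts: list[TranscriptRecord],
                              source: str = "genechain",
                              extra_mrna_attrs: dict[str, dict[str, str]] | None = None,
                              ) -> list[GffFeature]:
    """Serialize transcripts as mRNA + exon + CDS features with Parent links."""
    feats = []
    extra_mrna_attrs = extra_mrna_attrs or {}
    for t in transcripts:
        s, e = t.span
        attrs = {"ID": t.transcript_id}
        if t.source:
            attrs["source_tag"] = t.source
        attrs.update(extra_mrna_attrs.get(t.transcript_id, {}))
        feats.append(
            GffFeature(t.seqid, source, "mRNA", s, e, None, t.strand, None, attrs)
        )
        # phase bookkeeping walks the exons in transcript (5'->3') order
        ordered = t.exons if t.strand == "+" else list(reversed(t.exons))
        carried = 0
        for i, (xs, xe) in enumerate(ordered):
            feats.append(
                GffFeature(t.seqid, source, "exon", xs, xe, None, t.strand, None,
                           {"ID": f"{t.transcript_id}.exon{i + 1}",
                            "Parent": t.transcript_id})
            )
            phase = (3 - carried) % 3
            feats.append(
                GffFeature(t.seqid, source, "CDS", xs, xe, None, t.strand, phase,
                           {"ID": f"{t.transcript_id}.cds{i + 1}",
                            "Parent": t.transcript_id})
            )
            carried = (carried + (xe - xs + 1)) % 3
    return feats
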