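"""EST-side evidence: filter spliced alignments, cluster them by shared
splice sites, infer consensus introns, and build the minimal set of
non-mergeable transcript structures.

The intron caller is a consensus-and-canonical-shift procedure: member block
gaps that agree within ``boundary_tolerance`` are merged, each merged gap is
shifted within ``+-shift_window`` to a canonical GT..AG placement (choosing
the shift that maximizes the donor+acceptor PWM score when PWMs are
supplied, otherwise the smallest |shift|), and gaps that cannot be
canonicalized or lack support are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chainer import EvidenceIntron
from .formats_io import SplicedAlignment, TranscriptRecord
from .signal_content import score_pwm

__all__ = [
    "ClusterConfig",
    "EstCluster",
    "EstTranscript",
    "filter_alignments",
    "cluster_alignments",
    "infer_introns",
    "assemble_est_transcripts",
    "longest_orf",
    "mod3_profile",
]

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ClusterConfig:
    """Thresholds for alignment filtering, clustering and intron calling."""

    min_identity: float = 0.95      # 0.98 for human-style data
    min_coverage: float = 0.90      # strict: kept iff coverage > min_coverage
    boundary_tolerance: int = 3     # nt slack when matching splice sites
    min_intron_support: int = 1
    shift_window: int = 5           # nt search radius for GT..AG placement

    def __post_init__(self):
        if not (0.0 <= self.min_identity <= 1.0 and 0.0 <= self.min_coverage <= 1.0):
            raise ValueError("identity/coverage thresholds must lie in [0,1]")
        if self.boundary_tolerance < 0:
            raise ValueError("boundary_tolerance must be >= 0")


@dataclass
class EstCluster:
    cluster_id: str
    seqid: str
    strand: str
    members: list[SplicedAlignment] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [m.span[0] for m in self.members]
        ends = [m.span[1] for m in self.members]
        return min(starts), max(ends)


@dataclass
class EstTranscript:
    transcript_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    supporting_est_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def to_record(self) -> TranscriptRecord:
        return TranscriptRecord(self.transcript_id, self.seqid, self.strand,
                                list(self.exons), source="est")


def filter_alignments(alignments, config: ClusterConfig):
    """Retain alignments with identity >= min_identity and coverage strictly
    greater than min_coverage."""
    kept, discarded = [], []
    for a in alignments:
        if a.identity >= config.min_identity and a.coverage > config.min_coverage:
            kept.append(a)
        else:
            discarded.append(a)
    return kept, discarded


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_alignments(alignments, config: ClusterConfig):
    """Group alignments into clusters by shared splice sites.

    Spliced alignments sharing at least one splice site (same kind, same
    strand, positions within ``boundary_tolerance``) are linked; clusters
    are the connected components.  Unspliced alignments join the same-strand
    cluster with the largest span overlap, or form singletons.
    """
    alns = sorted(alignments, key=lambda a: (a.seqid, a.span, a.est_id))
    spliced = [i for i, a in enumerate(alns) if a.spliced]
    uf = _UnionFind(len(alns))

    # sites: (seqid, strand, kind, position, alignment index)
    sites = []
    for i in spliced:
        a = alns[i]
        for s, e in a.introns:
            sites.append((a.seqid, a.strand, "donor", s, i))
            sites.append((a.seqid, a.strand, "acceptor", e, i))
    sites.sort()
    for k in range(1, len(sites)):
        sq, st, kd, pos, i = sites[k]
        pq, pt, pk, ppos, j = sites[k - 1]
        if (sq, st, kd) == (pq, pt, pk) and pos - ppos <= config.boundary_tolerance:
            uf.union(i, j)

    comp: dict[int, list[int]] = {}
    for i in spliced:
        comp.setdefault(uf.find(i), []).append(i)

    clusters = []
    for root in sorted(comp, key=lambda r: (alns[r].seqid, alns[r].span)):
        members = [alns[i] for i in comp[root]]
        clusters.append((members[0].seqid, members[0].strand, members))

    # attach unspliced alignments by largest overlap on the same strand
    def overlap(span_a, span_b):
        return min(span_a[1], span_b[1]) - max(span_a[0], span_b[0]) + 1

    for i, a in enumerate(alns):
        if a.spliced:
            continue
        best, best_ov = None, 0
        for c in clusters:
            seqid, strand, members = c
            if seqid != a.seqid or strand != a.strand:
                continue
            span = (min(m.span[0] for m in members),
                    max(m.span[1] for m in members))
            ov = overlap(a.span, span)
            if ov > best_ov:
                best, best_ov = c, ov
        if best is not None and best_ov > 0:
            best[2].append(a)
        else:
            clusters.append((a.seqid, a.strand, [a]))

    clusters.sort(key=lambda c: (c[0], min(m.span[0] for m in c[2]),
                                 max(m.span[1] for m in c[2]), c[1]))
    return [
        EstCluster(cluster_id=f"cluster_{i + 1:04d}", seqid=seqid,
                   strand=strand, members=members)
        for i, (seqid, strand, members) in enumerate(clusters)
    ]


def _canonical_shift(genome, s, e, strand, window, pwms):
    """Best shift delta in [-window, window] making (s+d, e+d) canonical.

    Canonical means GT at the 5' intron end and AG at the 3' end on the
    intron's strand.  With PWMs the canonical shift maximizing
    donor+acceptor score wins; ties (and the no-PWM case) prefer the
    smallest |delta|, negative first.  Returns delta or None.
    """
    candidates = []
    for d in sorted(range(-window, window + 1), key=lambda d: (abs(d), d)):
        ss, ee = s + d, e + d
        if ss < 1 or ee > genome.length or ss >= ee:
            continue
        if strand == "+":
            donor_dinuc = genome.seq[ss - 1 : ss + 1]
            acc_dinuc = genome.seq[ee - 2 : ee]
            ok = donor_dinuc == "GT" and acc_dinuc == "AG"
        else:
            ok = (genome.seq[ee - 2 : ee] == "AC"
                  and genome.seq[ss - 1 : ss + 1] == "CT")
        if not ok:
            continue
        if pwms is None:
            return d
        donor_pos = ss if strand == "+" else ee
        acc_pos = ee - 1 if strand == "+" else ss + 1
        ds = score_pwm(pwms["donor"], genome, donor_pos, strand)
        as_ = score_pwm(pwms["acceptor"], genome, acc_pos, strand)
        if ds is None or as_ is None:
            score = float("-inf")
        else:
            score = ds + as_
        candidates.append((score, d))
    if not candidates:
        return None
    # deterministic: highest score; ties by smallest |delta|, negative first
    best_score = max(c[0] for c in candidates)
    tied = [d for sc, d in candidates if sc == best_score]
    tied.sort(key=lambda d: (abs(d), d))
    return tied[0]


def infer_introns(cluster: EstCluster, genome, config: ClusterConfig,
                  pwms=None):
    """Consensus introns of a cluster, canonicalized and support-counted.

    Returns a list of EvidenceIntron; also records, on the cluster's
    members' behalf, which member gap maps to which refined intron via the
    returned mapping attribute (see :func:`assemble_est_transcripts`).
    """
    gaps = []  # (start, end, member index)
    for mi, m in enumerate(cluster.members):
        for g in m.introns:
            gaps.append((g[0], g[1], mi))
    if not gaps:
        return []

    order = sorted(range(len(gaps)), key=lambda i: (gaps[i][0], gaps[i][1]))
    uf = _UnionFind(len(gaps))
    tol = config.boundary_tolerance
    for a in range(len(order)):
        ia = order[a]
        for b in range(a + 1, len(order)):
            ib = order[b]
            if gaps[ib][0] - gaps[ia][0] > tol:
                break
            if abs(gaps[ib][1] - gaps[ia][1]) <= tol:
                uf.union(ia, ib)

    groups: dict[int, list[int]] = {}
    for i in range(len(gaps)):
        groups.setdefault(uf.find(i), []).append(i)

    introns = []
    gap_to_intron: dict[tuple[int, int], tuple[int, int] | None] = {}
    for root in sorted(groups, key=lambda r: (gaps[r][0], gaps[r][1])):
        idxs = groups[root]
        # modal boundary pair, ties to the smallest coordinates
        votes: dict[tuple[int, int], int] = {}
        for i in idxs:
            key = (gaps[i][0], gaps[i][1])
            votes[key] = votes.get(key, 0) + 1
        (s, e), _ = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        delta = _canonical_shift(genome, s, e, cluster.strand,
                                 config.shift_window, pwms)
        support = len(idxs)
        raw_keys = {(gaps[i][0], gaps[i][1]) for i in idxs}
        if delta is None or support < config.min_intron_support:
            for k in raw_keys:
                gap_to_intron[k] = None
            continue
        refined = (s + delta, e + delta)
        for k in raw_keys:
            gap_to_intron[k] = refined
        introns.append(
            EvidenceIntron(seqid=cluster.seqid, start=refined[0],
                           end=refined[1], strand=cluster.strand,
                           support=support, source="est")
        )
    introns.sort(key=lambda i: (i.start, i.end))
    # deduplicate introns that canonicalized to the same position
    merged: dict[tuple, EvidenceIntron] = {}
    for it in introns:
        if it.key in merged:
            merged[it.key].support += it.support
        else:
            merged[it.key] = it
    result = sorted(merged.values(), key=lambda i: (i.start, i.end))
    cluster_map = {"gap_to_intron": gap_to_intron}
    # stash on the cluster for downstream transcript assembly
    cluster.__dict__.setdefault("_intron_map", {}).update(cluster_map["gap_to_intron"])
    return result


def _member_structure(member: SplicedAlignment, gap_map):
    """Re-express a member's blocks over refined introns.

    Returns (exons, introns) or None when any of the member's gaps was
    dropped during canonicalization.
    """
    span_s, span_e = member.span
    refined = []
    for g in member.introns:
        r = gap_map.get(g)
        if r is None:
            return None
        refined.append(r)
    refined = sorted(set(refined))
    exons = []
    cur = span_s
    for s, e in refined:
        if s <= cur or e >= span_e:
            return None  # shift pushed the intron outside the member span
        exons.append((cur, s - 1))
        cur = e + 1
    exons.append((cur, span_e))
    return exons


def _structures_compatible(x, y):
    """True when two exon structures agree over their overlap region.

    x, y: (exons, introns, ...) tuples of sorted interval lists.  Agreement
    means every intron of one overlapping the shared region is contained in
    it and matched exactly by the other.
    """
    ex_x, ex_y = x, y
    ox = (max(ex_x[0][0], ex_y[0][0]), min(ex_x[-1][1], ex_y[-1][1]))
    if ox[0] > ox[1]:
        return False  # disjoint structures cannot be confirmed continuous

    def introns_of(exons):
        return [
            (exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)
        ]

    def over(introns):
        out = []
        for s, e in introns:
            if e < ox[0] or s > ox[1]:
                continue
            if s < ox[0] or e > ox[1]:
                return None  # straddles the overlap edge: conflicting exon
            out.append((s, e))
        return out

    ix = over(introns_of(ex_x))
    iy = over(introns_of(ex_y))
    if ix is None or iy is None:
        return False
    return ix == iy


def _merge_structures(x, y):
    """Union of two compatible structures (exons recomputed from introns)."""
    span = (min(x[0][0], y[0][0]), max(x[-1][1], y[-1][1]))

    def introns_of(exons):
        return [
            (exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)
        ]

    introns = sorted(set(introns_of(x)) | set(introns_of(y)))
    exons = []
    cur = span[0]
    for s, e in introns:
        exons.append((cur, s - 1))
        cur = e + 1
    exons.append((cur, span[1]))
    return exons


def assemble_est_transcripts(cluster: EstCluster, introns):
    """Greedy merge of member structures to the non-mergeable fixpoint.

    Members are re-expressed over the refined introns (members whose gaps
    failed canonicalization are skipped), then merged longest-first until no
    two remaining structures are compatible.  Deterministic.
    """
    gap_map = dict(getattr(cluster, "_intron_map", {}))
    for it in introns:
        # identity mapping for gaps that already match refined introns
        gap_map.setdefault((it.start, it.end), (it.start, it.end))

    structures = []  # (exons, supporting ids)
    for m in cluster.members:
        exons = _member_structure(m, gap_map)
        if exons is not None:
            structures.append((exons, {m.est_id}))

    def sort_key(t):
        return (-(t[0][-1][1] - t[0][0][0]), t[0][0][0], tuple(t[0]))

    structures.sort(key=sort_key)
    while True:
        merged: list[tuple] = []
        changed = False
        for exons, ids in structures:
            for k, (m_ex, m_ids) in enumerate(merged):
                if _structures_compatible(m_ex, exons):
                    merged[k] = (_merge_structures(m_ex, exons), m_ids | ids)
                    changed = True
                    break
            else:
                merged.append((exons, ids))
        structures = sorted(merged, key=sort_key)
        if not changed:
            break

    out = []
    for i, (exons, ids) in enumerate(structures):
        out.append(
            EstTranscript(
                transcript_id=f"{cluster.cluster_id}.t{i + 1}",
                seqid=cluster.seqid,
                strand=cluster.strand,
                exons=exons,
                supporting_est_ids=sorted(ids),
            )
        )
    return out


def longest_orf(transcript_seq: str):
    """Longest ATG..stop open reading frame over the three forward frames.

    Returns (start_offset, end_offset, frame), 1-based inclusive with the
    stop codon included, or None.  Equal lengths break to the 5'-most start.
    """
    seq = transcript_seq.upper()
    n = len(seq)
    best = None  # (length, start) -> offsets
    for f in range(3):
        start = None
        for i in range(f, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOPS:
                length = i + 3 - start
                if best is None or length > best[0] or (
                    length == best[0] and start < best[1]
                ):
                    best = (length, start)
                start = None
    if best is None:
        return None
    length, start = best
    return (start + 1, start + length, start % 3)


def extract_cds(genome, transcript: EstTranscript):
    """Longest-ORF CDS of an EST transcript, mapped back to genomic exons.

    Returns a TranscriptRecord (source "cds") or None when the spliced
    sequence holds no complete ORF.
    """
    tx_exons = (transcript.exons if transcript.strand == "+"
                else list(reversed(transcript.exons)))
    seq = "".join(
        genome.subseq(s, e, transcript.strand) for s, e in tx_exons
    )
    orf = longest_orf(seq)
    if orf is None:
        return None
    a, b, _frame = orf  # 1-based inclusive in transcript coords
    blocks = []
    cum = 0
    for s, e in tx_exons:
        elen = e - s + 1
        lo = max(a - 1, cum)
        hi = min(b - 1, cum + elen - 1)
        if lo <= hi:
            if transcript.strand == "+":
                blocks.append((s + (lo - cum), s + (hi - cum)))
            else:
                blocks.append((e - (hi - cum), e - (lo - cum)))
        cum += elen
    blocks.sort()
    return TranscriptRecord(
        transcript_id=f"{transcript.transcript_id}.cds",
        seqid=transcript.seqid, strand=transcript.strand,
        exons=blocks, source="cds",
    )


def mod3_profile(introns):
    """Fractions of intron lengths congruent to 0, 1, 2 modulo 3."""
    lengths = []
    for it in introns:
        if isinstance(it, int):
            lengths.append(it)
        elif hasattr(it, "length"):
            lengths.append(it.length)
        else:
            s, e = it
            lengths.append(e - s + 1)
    if not lengths:
        raise ValueError("mod3_profile requires at least one intron")
    n = len(lengths)
    counts = [0, 0, 0]
    for x in lengths:
        counts[x % 3] += 1
    return tuple(c / n for c in counts)
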