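"""Exon chaining: assemble scored exon candidates into gene structures.

The assembler maximizes the summed score of the chained exons plus a bonus
for every join whose implied intron exactly matches an EST-derived evidence
intron.  With the (default) dominating bonus the objective is effectively
lexicographic — number of matched evidence introns first, raw score second —
so exons whose splice sites are compatible with an evidence intron are always
joined when the join conforms to a valid gene model.  Evidence introns
therefore act as anchors in the chaining without ever creating exons of
their own.

Both strands are assembled in a single pass; gene structures may not overlap
(across strands either) and consecutive genes must be separated by at least
``min_intergenic`` bases.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

__all__ = [
    "GeneModelRules",
    "EvidenceIntron",
    "TranscriptModel",
    "GenePrediction",
    "validate_evidence",
    "assemble",
    "oracle_assemble",
    "objective_value",
    "inject_cds_evidence",
    "DEFAULT_INTRON_BONUS",
]

DEFAULT_INTRON_BONUS = 1e6

_STANDARD_TRANSITIONS = frozenset(
    {
        ("First", "Internal"),
        ("First", "Terminal"),
        ("Internal", "Internal"),
        ("Internal", "Terminal"),
    }
)


@dataclass
class GeneModelRules:
    """Grammar and geometry constraints for assembled gene structures."""

    allowed_transitions: frozenset = _STANDARD_TRANSITIONS
    min_intron_len: int = 30
    max_intron_len: int = 5000
    min_intergenic: int = 100
    min_exon_len: int = 10
    max_exon_len: int = 10000
    allow_partial_genes: bool = False

    def __post_init__(self):
        self.allowed_transitions = frozenset(
            tuple(t) for t in self.allowed_transitions
        )
        if self.min_intron_len < 4:
            raise ValueError("min_intron_len must be >= 4")
        if self.max_intron_len <= self.min_intron_len:
            raise ValueError("max_intron_len must exceed min_intron_len")


@dataclass
class EvidenceIntron:
    """An intron with EST support; start/end are first/last intronic bases."""

    seqid: str
    start: int
    end: int
    strand: str
    support: int = 1
    source: str = "est"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def key(self) -> tuple:
        return (self.seqid, self.start, self.end, self.strand)


@dataclass
class TranscriptModel:
    """An assembled chain of exon candidates (genomic order)."""

    transcript_id: str
    exons: list  # ExonCandidate-like, ordered by start
    total_score: float
    evidence_intron_count: int

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i].end + 1, self.exons[i + 1].start - 1)
            for i in range(len(self.exons) - 1)
        ]

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(e.start, e.end) for e in self.exons]


@dataclass
class GenePrediction:
    gene_id: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)


def validate_evidence(introns, genome, rules: GeneModelRules):
    """Screen raw evidence introns; merge duplicates, summing support.

    Returns ``(accepted, rejected)`` where rejected entries are
    ``(intron, reason)`` pairs.  Rejection is data, not failure.
    """
    merged: dict[tuple, EvidenceIntron] = {}
    rejected = []
    for it in introns:
        if it.strand not in ("+", "-"):
            rejected.append((it, "undefined strand"))
            continue
        if it.start < 1 or it.end > genome.length or it.start > it.end:
            rejected.append((it, "coordinates outside the genome"))
            continue
        if it.length < rules.min_intron_len:
            rejected.append((it, "below min_intron_len"))
            continue
        if it.length > rules.max_intron_len:
            rejected.append((it, "above max_intron_len"))
            continue
        if it.key in merged:
            merged[it.key].support += it.support
        else:
            merged[it.key] = EvidenceIntron(
                it.seqid, it.start, it.end, it.strand, it.support, it.source
            )
    accepted = sorted(merged.values(), key=lambda i: i.key)
    return accepted, rejected


def _is_gene_initial(c, rules: GeneModelRules) -> bool:
    """Can c be the genomically leftmost exon of a gene?"""
    if c.exon_class == "Single":
        return True
    if c.strand == "+":
        ok = c.exon_class == "First"
    else:
        ok = c.exon_class == "Terminal"
    if ok:
        return True
    return rules.allow_partial_genes and c.exon_class == "Internal"


def _is_gene_final(c, rules: GeneModelRules) -> bool:
    """Can c be the genomically rightmost exon of a gene?"""
    if c.exon_class == "Single":
        return True
    if c.strand == "+":
        ok = c.exon_class == "Terminal"
    else:
        ok = c.exon_class == "First"
    if ok:
        return True
    return rules.allow_partial_genes and c.exon_class == "Internal"


def _join_ok(u, v, rules: GeneModelRules) -> bool:
    """May u (left) and v (right) be consecutive exons of one transcript?"""
    if u.seqid != v.seqid or u.strand != v.strand:
        return False
    if u.exon_class == "Single" or v.exon_class == "Single":
        return False
    ilen = v.start - u.end - 1
    if not (rules.min_intron_len <= ilen <= rules.max_intron_len):
        return False
    if u.strand == "+":
        upstream, downstream = u, v
    else:  # transcription right-to-left
        upstream, downstream = v, u
    if (upstream.exon_class, downstream.exon_class) not in rules.allowed_transitions:
        return False
    return upstream.remainder == downstream.frame


def _predictions_from_chains(chains, evidence_keys, gene_prefix="gene"):
    """Package exon chains (genomic order) as GenePrediction objects."""
    chains = sorted(chains, key=lambda ch: (ch[0].seqid, ch[0].start, ch[0].end))
    preds = []
    for gi, chain in enumerate(chains, 1):
        ev = sum(
            1
            for i in range(len(chain) - 1)
            if (chain[i].seqid, chain[i].end + 1, chain[i + 1].start - 1,
                chain[i].strand) in evidence_keys
        )
        t = TranscriptModel(
            transcript_id=f"{gene_prefix}_{gi:05d}.t1",
            exons=list(chain),
            total_score=sum(e.score for e in chain),
            evidence_intron_count=ev,
        )
        preds.append(
            GenePrediction(gene_id=f"{gene_prefix}_{gi:05d}", strand=t.strand,
                           transcripts=[t])
        )
    return preds


def _sort_key(c):
    return (c.end, c.start, c.exon_class, c.frame, c.strand)


class JoinIndex:
    """Precomputed join-feasibility graph over a fixed candidate list.

    Join feasibility (strand, class transition, frame continuity, intron
    length bounds) does not depend on the evidence, so repeated assemblies
    over the same candidates — e.g. the intron-titration experiment — can
    share one index.  Every feasible (u, v) pair gets a pair id, and introns
    are mapped to the pair ids they would reward.
    """

    def __init__(self, candidates, rules: GeneModelRules):
        self.rules = rules
        self.n_pairs = 0
        self.by_seqid: dict[str, dict] = {}
        for c in candidates:
            self.by_seqid.setdefault(c.seqid, {"cands": []})["cands"].append(c)
        for seqid in sorted(self.by_seqid):
            entry = self.by_seqid[seqid]
            cands = sorted(entry["cands"], key=_sort_key)
            ends = [c.end for c in cands]
            joins = []
            by_start: dict[int, list[int]] = {}
            for i, c in enumerate(cands):
                by_start.setdefault(c.start, []).append(i)
                lo = bisect_left(ends, c.start - rules.max_intron_len - 1)
                hi = bisect_right(ends, c.start - rules.min_intron_len - 1)
                row = [j for j in range(lo, hi) if _join_ok(cands[j], c, rules)]
                self.n_pairs += len(row)
                joins.append(row)
            entry["cands"] = cands
            entry["ends"] = ends
            entry["joins"] = joins
            entry["by_start"] = by_start

    def bonus_map(self, seqid: str, evidence_keys) -> dict[int, set[int]]:
        """Per downstream candidate, the join partners rewarded by evidence."""
        entry = self.by_seqid[seqid]
        cands, joins, by_start = entry["cands"], entry["joins"], entry["by_start"]
        out: dict[int, set[int]] = {}
        for (sq, s, e, strand) in evidence_keys:
            if sq != seqid:
                continue
            for i in by_start.get(e + 1, ()):
                if cands[i].strand != strand:
                    continue
                js = {
                    j for j in joins[i]
                    if cands[j].end == s - 1 and cands[j].strand == strand
                }
                if js:
                    out.setdefault(i, set()).update(js)
        return out


def _assemble_seqid(cands, evidence_keys, rules: GeneModelRules,
                    intron_bonus: float, joins=None, bonus_pairs=None):
    """DP over one seqid's candidates (already sorted by end); returns chains."""
    n = len(cands)
    ends = [c.end for c in cands]

    dp = [0.0] * n  # cumulative objective of best structure set ending at i
    back = [None] * n  # ("start", prev_closed_index_or_None) | ("join", j)
    # closed prefix: running best cumulative value over gene-final candidates,
    # queryable by end coordinate
    c_ends: list[int] = []
    c_best: list[float] = []
    c_idx: list[int | None] = []

    eps = 1e-9
    for i, c in enumerate(cands):
        best_val = None
        best_bp = None
        if _is_gene_initial(c, rules):
            prev_val, prev_idx = 0.0, None
            limit = c.start - rules.min_intergenic - 1
            k = bisect_right(c_ends, limit) - 1
            if k >= 0 and c_best[k] > prev_val:
                prev_val, prev_idx = c_best[k], c_idx[k]
            best_val = prev_val + c.score
            best_bp = ("start", prev_idx)
        if joins is not None:
            bset = bonus_pairs.get(i) if bonus_pairs else None
            if bset is None:
                for j in joins[i]:
                    if back[j] is None:
                        continue
                    val = dp[j] + c.score
                    if best_val is None or val > best_val + eps:
                        best_val, best_bp = val, ("join", j)
            else:
                for j in joins[i]:
                    if back[j] is None:
                        continue
                    val = dp[j] + c.score
                    if j in bset:
                        val += intron_bonus
                    if best_val is None or val > best_val + eps:
                        best_val, best_bp = val, ("join", j)
        else:
            # joins: u.end in [c.start - max_intron - 1, c.start - min_intron - 1]
            lo = bisect_left(ends, c.start - rules.max_intron_len - 1)
            hi = bisect_right(ends, c.start - rules.min_intron_len - 1)
            for j in range(lo, hi):
                u = cands[j]
                if back[j] is None or not _join_ok(u, c, rules):
                    continue
                val = dp[j] + c.score
                if (u.seqid, u.end + 1, c.start - 1, u.strand) in evidence_keys:
                    val += intron_bonus
                if best_val is None or val > best_val + eps:
                    best_val, best_bp = val, ("join", j)
        if best_val is None:
            continue  # unreachable candidate
        dp[i] = best_val
        back[i] = best_bp
        if _is_gene_final(c, rules):
            run_best = c_best[-1] if c_best else 0.0
            if dp[i] > run_best + eps:
                c_ends.append(c.end)
                c_best.append(dp[i])
                c_idx.append(i)
            else:
                c_ends.append(c.end)
                c_best.append(run_best)
                c_idx.append(c_idx[-1] if c_idx else None)

    best_idx = None
    if c_best and c_best[-1] > eps:
        best_idx = c_idx[-1]
    chains = []
    i = best_idx
    while i is not None:
        chain = []
        while True:
            chain.append(cands[i])
            kind, j = back[i]
            if kind == "start":
                i = j
                break
            i = j
        chains.append(list(reversed(chain)))
    return chains


def assemble(candidates, evidence_introns, rules: GeneModelRules,
             intron_bonus: float = DEFAULT_INTRON_BONUS,
             join_index: JoinIndex | None = None):
    """Chain candidates into the objective-maximal set of gene structures.

    Objective: sum of exon scores plus ``intron_bonus`` for every join whose
    implied intron exactly matches an evidence intron (boundaries and strand).
    Returns a list of GenePrediction, one transcript each, in genomic order.
    ``join_index`` (a :class:`JoinIndex` built over the same candidates and
    rules) makes repeated assemblies over one candidate set cheap.
    """
    if not candidates:
        return []
    evidence_keys = {e.key for e in evidence_introns}
    if evidence_keys and intron_bonus > 0:
        total_abs = sum(abs(c.score) for c in candidates) + 1.0
        if intron_bonus <= total_abs:
            warnings.warn(
                f"intron_bonus={intron_bonus} does not dominate the summed "
                f"candidate scores ({total_abs:.1f}); the evidence-count-first "
                "objective is not guaranteed",
                stacklevel=2,
            )

    chains = []
    if join_index is not None:
        for seqid in sorted(join_index.by_seqid):
            entry = join_index.by_seqid[seqid]
            chains.extend(
                _assemble_seqid(entry["cands"], evidence_keys, rules,
                                intron_bonus, joins=entry["joins"],
                                bonus_pairs=join_index.bonus_map(
                                    seqid, evidence_keys))
            )
    else:
        by_seqid: dict[str, list] = {}
        for c in candidates:
            by_seqid.setdefault(c.seqid, []).append(c)
        for seqid in sorted(by_seqid):
            cands = sorted(by_seqid[seqid], key=_sort_key)
            chains.extend(
                _assemble_seqid(cands, evidence_keys, rules, intron_bonus)
            )
    return _predictions_from_chains(chains, evidence_keys)


def objective_value(predictions, evidence_introns,
                    intron_bonus: float = DEFAULT_INTRON_BONUS) -> float:
    """Recompute the chaining objective of a prediction set from scratch."""
    evidence_keys = {e.key for e in evidence_introns}
    total = 0.0
    for g in predictions:
        for t in g.transcripts:
            total += sum(e.score for e in t.exons)
            for s, e in t.introns:
                if (t.seqid, s, e, t.strand) in evidence_keys:
                    total += intron_bonus
    return total


def evidence_intron_count(predictions, evidence_introns) -> int:
    evidence_keys = {e.key for e in evidence_introns}
    n = 0
    for g in predictions:
        for t in g.transcripts:
            for s, e in t.introns:
                if (t.seqid, s, e, t.strand) in evidence_keys:
                    n += 1
    return n


def oracle_assemble(candidates, evidence_introns, rules: GeneModelRules,
                    intron_bonus: float = DEFAULT_INTRON_BONUS):
    """Exhaustive reference assembler for small instances (tests only).

    Enumerates every rule-valid chain, then every compatible chain set, and
    returns the objective-maximal set.  Refuses more than 15 candidates.
    """
    if len(candidates) > 15:
        raise ValueError("oracle_assemble refuses instances with > 15 candidates")
    if not candidates:
        return []
    evidence_keys = {e.key for e in evidence_introns}
    cands = sorted(candidates, key=lambda c: (c.seqid, c.start, c.end, c.frame))

    # all valid complete chains
    chains = []

    def extend(chain):
        last = chain[-1]
        if _is_gene_final(last, rules):
            chains.append(list(chain))
        for v in cands:
            if v.start > last.end and _join_ok(last, v, rules):
                chain.append(v)
                extend(chain)
                chain.pop()

    for c in cands:
        if _is_gene_initial(c, rules):
            extend([c])

    def chain_value(chain):
        val = sum(e.score for e in chain)
        for i in range(len(chain) - 1):
            key = (chain[i].seqid, chain[i].end + 1, chain[i + 1].start - 1,
                   chain[i].strand)
            if key in evidence_keys:
                val += intron_bonus
        return val

    vals = [chain_value(ch) for ch in chains]
    spans = [(ch[0].seqid, ch[0].start, ch[-1].end) for ch in chains]
    order = sorted(range(len(chains)), key=lambda k: spans[k])

    best = {"val": 0.0, "set": []}

    def compatible(k, chosen):
        sk, ak, bk = spans[k]
        for m in chosen:
            sm, am, bm = spans[m]
            if sm != sk:
                continue
            if not (bk + rules.min_intergenic < am or bm + rules.min_intergenic < ak):
                return False
        return True

    def pick(pos, chosen, val):
        if val > best["val"] + 1e-9:
            best["val"] = val
            best["set"] = list(chosen)
        if pos == len(order):
            return
        # optimistic bound: add all remaining positive values
        bound = val + sum(max(v, 0.0) for v in (vals[order[q]] for q in range(pos, len(order))))
        if bound <= best["val"] + 1e-9:
            return
        k = order[pos]
        if compatible(k, chosen):
            chosen.append(k)
            pick(pos + 1, chosen, val + vals[k])
            chosen.pop()
        pick(pos + 1, chosen, val)

    pick(0, [], 0.0)
    return _predictions_from_chains([chains[k] for k in best["set"]], evidence_keys)


def inject_cds_evidence(cds_transcripts, candidates, boost: float,
                        model=None, genome=None):
    """Add EST-derived CDS structures as boosted exon candidates.

    Each CDS exon becomes an ExonCandidate of the appropriate class with
    score ``boost`` (plus its coding-model score when ``model`` and ``genome``
    are given); the CDS introns join the evidence set.  A CDS exon identical
    to an existing candidate raises that candidate's score to the boosted
    value instead of duplicating it.

    Returns ``(augmented_candidates, evidence_introns, rejected)`` where
    rejected entries are ``(transcript, reason)`` pairs.
    """
    from .exon_builder import ExonCandidate, SignalSite
    from .signal_content import score_coding

    augmented = [c for c in candidates]
    index = {
        (c.seqid, c.start, c.end, c.strand, c.exon_class, c.frame): i
        for i, c in enumerate(augmented)
    }
    evidence = []
    rejected = []
    for t in cds_transcripts:
        total = sum(e - s + 1 for s, e in t.exons)
        if total % 3 != 0:
            rejected.append((t, "CDS length not a multiple of 3"))
            continue
        ordered = t.exons if t.strand == "+" else list(reversed(t.exons))
        n = len(ordered)
        frame = 0
        entries = []
        ok = True
        for i, (s, e) in enumerate(ordered):
            if n == 1:
                klass = "Single"
            elif i == 0:
                klass = "First"
            elif i == n - 1:
                klass = "Terminal"
            else:
                klass = "Internal"
            if klass in ("First", "Single") and frame != 0:
                ok = False
                break
            length = e - s + 1
            if length < frame:
                ok = False
                break
            entries.append((s, e, klass, frame))
            frame = (3 - ((length - frame) % 3)) % 3
        if not ok or frame != 0:
            rejected.append((t, "exon chain violates frame arithmetic"))
            continue
        for s, e, klass, fr in entries:
            score = boost
            if model is not None and genome is not None:
                score += score_coding(model, genome, s, e, t.strand, fr)
            key = (t.seqid, s, e, t.strand, klass, fr)
            if key in index:
                i = index[key]
                old = augmented[i]
                if score > old.score:
                    augmented[i] = ExonCandidate(
                        seqid=old.seqid, start=old.start, end=old.end,
                        strand=old.strand, exon_class=old.exon_class,
                        frame=old.frame, score=score,
                        five_site=old.five_site, three_site=old.three_site,
                    )
                continue
            site5 = SignalSite("evidence", s, t.strand, 0.0)
            site3 = SignalSite("evidence", e, t.strand, 0.0)
            cand = ExonCandidate(
                seqid=t.seqid, start=s, end=e, strand=t.strand,
                exon_class=klass, frame=fr, score=score,
                five_site=site5, three_site=site3,
            )
            index[key] = len(augmented)
            augmented.append(cand)
        for s, e in t.introns:
            evidence.append(
                EvidenceIntron(t.seqid, s, e, t.strand, support=1, source="cds")
            )
    return augmented, evidence, rejected
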