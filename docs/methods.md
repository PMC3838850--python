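# Methods

This note documents the models, the tunable parameters, the synthetic-data
generator, and the numerical/design choices behind genechain, in the order
data flows through the pipeline.

## Signal and content models

Splice donor, splice acceptor and translation start are scored with
position weight matrices over fixed windows:

| signal   | window                            | width | core |
|----------|-----------------------------------|-------|------|
| donor    | 3 exonic + GT + 4 intronic        | 9     | GT   |
| acceptor | 18 intronic + AG + 3 exonic       | 23    | AG   |
| start    | 6 upstream + ATG + 3 coding       | 12    | ATG  |

Entries are log₂((count + π)/(n + 4π)/q_b) with pseudocount π = 0.5 and a
background q estimated from intergenic sequence. Stop codons are matched
exactly ({TAA, TAG, TGA}) and contribute score 0; they carry no PWM.
Non-canonical splice dinucleotides (GC–AG, AT–AC) are out of scope. Any
window containing N, or running off the sequence, yields "no signal".

Coding potential is a frame-specific Markov chain of order 4 (default,
configurable) against a single frame-agnostic background chain, both
pseudocount-smoothed. The context of a scored base is the k genomic bases
immediately 5′ of it **on the same strand, even when they lie outside the
scored interval**; bases without a full context, or with N in the window,
contribute zero. This convention makes interval scores exactly additive
across a split, which in turn lets exon enumeration use three cumulative
per-phase score arrays that agree with the direct interval scorer to
floating-point roundoff — the enumerator and the reference scorer cannot
drift apart.

`frame` throughout is the number of bases at an interval's 5′ end that
complete the codon begun upstream (the GFF phase convention); an exon of
length L in frame f carries remainder r = (3 − ((L − f) mod 3)) mod 3 into
the downstream intron, and a join requires upstream remainder = downstream
frame.

## Exon candidates

Candidates are enumerated per strand in strand-apparent coordinates (the
reverse complement for minus) and reflected back, guaranteeing strand
mirror symmetry by construction. Classes: First (start..donor), Internal
(acceptor..donor), Terminal (acceptor..stop, stop codon included), Single
(start..stop). An in-frame stop strictly inside the reading excludes the
candidate, so a Terminal/Single exon always ends at the *first* in-frame
stop after its 5′ boundary. Stops assembled across an intron junction are
not checked — the classic limitation of linear-join chaining, accepted
deliberately to keep join feasibility a local test.

Candidate score = 5′ signal + 3′ signal + coding score + **exon weight**.
The exon weight (default −12 bits) prices the inclusion of an exon: chains
of weak decoy exons then score negative in total and drop out of the
optimal structure set, while a weak true exon (the score floor of planted
true exons sits near +4 bits raw) survives as a candidate — the admission
threshold is a permissive −25 — and is rescued by its chain context or an
evidence anchor. This is the same calibration role the exon-weight
parameter plays in classic ab initio finders. Exon length bounds default
to 10..10,000 bp.

## Chaining

The assembler maximizes Σ exon scores + B·(matched evidence introns) over
all sets of non-overlapping, grammar-valid chains, with genes separated by
at least `min_intergenic` bases (enforced across strands: one prediction
per locus). Evidence matching is exact on both intron boundaries and the
strand — tolerance belongs to the EST module, which has already refined
boundaries; exactness keeps the DP deterministic.

B defaults to 10⁶, which realizes the intended lexicographic objective
(evidence count first, then score) whenever B exceeds the summed absolute
candidate scores; the assembler asserts this at run time and warns when
the assertion binds. On very large candidate sets the warning fires, but
the bound is extremely conservative: competing chains over one locus
differ by tens of bits, so 10⁶ still dominates in practice. Whether the
original modified chainer forced evidence joins as a hard constraint or a
dominant soft one is not documented; the dominant-bonus reading was chosen
because it degrades gracefully when evidence conflicts with the gene
grammar (a hard constraint could render a locus unsolvable).

The DP is the best-chain-ending-at-candidate recurrence with a running
prefix maximum over closed (gene-final) candidates, O(candidates × joins
within the intron-length window). A `JoinIndex` precomputes the
feasibility graph once per candidate set, which the titration experiment
reuses across its ~50 assemblies. Ties in the objective resolve to the
first-found option under a fixed candidate ordering (end, start, class,
frame), making output deterministic. An exhaustive oracle
(`oracle_assemble`, ≤ 15 candidates) enumerates every valid chain set and
certifies both optimality and evidence maximality in the test suite.

`inject_cds_evidence` turns EST-derived CDS structures into boosted
candidates (default boost 100, plus the coding score when a model is
supplied); a CDS exon identical to an existing candidate raises that
candidate's score instead of duplicating it, and CDS introns join the
evidence set.

## EST evidence

Alignments are kept iff identity ≥ `min_identity` (default 0.95; 0.98 is
the human-style preset) **and** coverage > `min_coverage` (0.90, strict).
Spliced alignments sharing a splice site within `boundary_tolerance`
(default 3 nt — the magnitude of "minimal mismatch" is not documented
anywhere authoritative, so it is surfaced in the config) are linked;
clusters are the connected components, so near-site tolerance chains
transitively. Unspliced alignments attach to the same-strand cluster with
the largest span overlap or become singletons; they contribute no introns.

Within a cluster, member block gaps agreeing within the tolerance merge
into one consensus intron (modal boundary pair, ties to the smaller
coordinates), then shift within ±`shift_window` (default 5 nt) to a
canonical GT..AG placement — the shift maximizing donor+acceptor PWM score
when PWMs are available, else the smallest |shift|. Gaps that cannot be
canonicalized, or with support below `min_intron_support`, are dropped.
This consensus-and-shift caller deliberately replaces a full multiple
EST-genome alignment with boundary refinement; it honors the same
input/output contract (clusters in, canonical support-counted introns
out), which is all the downstream assembler consumes.

Cluster members re-expressed over the refined introns are merged greedily,
longest-first, to a fixpoint in which no two structures agree on their
entire overlap; the result is the minimal non-mergeable transcript set.
Two structures are mergeable iff every intron of one overlapping the
shared region lies inside it and is matched exactly by the other.

## Isoform modes

AS1: output = EST transcripts ∪ predictions with no same-strand exonic
overlap (≥ 1 bp) to any EST transcript. AS2: loci of overlapping EST CDSs
are spread over n bins (n = largest per-locus isoform count, longest-first
order, cyclic re-use so each bin covers every locus — the deterministic
reading of "reassigned to empty bins"); each bin's CDSs are injected as
evidence together with the *unassociated* introns (evidence introns not
contained in any CDS span — the minimal reading of an otherwise undefined
term), the assembler runs per bin, and exact duplicate exon chains are
removed. Near-duplicates are retained by design; dedup is exact-structure
equality only.

## Evaluation

SP is computed as TP/(TP+FP) at every level, although the classical
write-up of these measures prints SP = TN/(TN+FP): a true-negative count
is undefined for exon/intron/transcript features, and published accuracy
tables in this field are only consistent with the TP-based form. W and M
are the fractions of predicted (resp. annotated) features with zero
same-strand overlap to the other side. Gene level: an annotated gene
counts as found iff a predicted gene overlaps it by ≥ 1 exonic bp on the
same strand; because overlap matching is asymmetric, the gene report
stores both matched counts and the count identities TP+FN = annotated,
TP+FP = predicted are exact (and tested) at the exact-match levels.
Transcript level requires the complete exon chain to match exactly;
structures are deduplicated first. Intron level compares distinct intron
sets across transcripts. 0/0 ratios are reported as 0 with a `degenerate`
flag, never NaN. BTP mode first builds a greedy maximum-weight one-to-one
transcript pairing by shared coding-base overlap, then attaches unmatched
transcripts to already-matched partners when the overlap exceeds half
their own coding length (the split/join cases; the threshold is not
documented anywhere and is configurable), and recomputes all levels on
the paired subsets.

## Synthetic data

The generator emulates multi-gene genomes: codon-biased stop-free CDS
(fixed mild codon-usage weights), canonical introns carrying planted
consensus contexts (GTAAGT-like donor tail, pyrimidine tract + CAG box
before the acceptor, 85% per-base consensus probability), a Kozak-like
context before each start, genes on both strands, ≥ 300 bp intergenic
gaps, and optional exon-skipping isoforms whose skipped exon is
codon-aligned so the skip variant stays stop-free. ESTs are contiguous
windows of mature isoforms emitted as **exact truth-block projections**:
no aligner is in the loop, and the EST error rate perturbs only the
reported identity attribute, never block coordinates. Coverage is the
window/transcript length ratio. Defaults: 100 kb, 30 genes, 3–6 exons of
80–250 bp, introns 50–200 bp, isoform probability 0.2, 4–10 ESTs per gene
of 500–4000 nt, error rate 0.005, 10% unspliced.

What passing tests therefore do *not* show: robustness to misaligned
blocks, to non-canonical splice sites, to UTRs (all exons here are
coding), to sequencing-chemistry error patterns, or to paralogous gene
families. They do show that every stage is correct under its own model
assumptions, and that the chaining layer is exactly optimal regardless of
where candidates and evidence come from.

`train_from_truth` closes the loop: PWMs from annotated splice windows,
coding chain from spliced CDS vs intergenic background, intron length
bounds from the observed distribution (×0.8 lower, ×1.25 + 10 upper
margins), and per-signal thresholds at (minimum training-site score − 5)
— all quantities a practitioner would derive from a training annotation,
none hand-set per experiment.

## Problem sizes and numerical choices

The bundled experiments use 30 kb/8-gene genomes for closed-loop recovery
checks and a 100 kb/30-gene genome with 10 replicates per evidence
fraction for the titration; these sizes exercise every code path
(multi-gene, both strands, isoforms) while the whole suite and the
acceptance script each run in about a minute. Objective comparisons
against the exhaustive oracle use an absolute tolerance of 10⁻⁶ (scores
are float64 sums of a few hundred terms). The intron mod-3 diagnostic in
the tests samples a length range spanning a multiple of three (50..199)
so the uniform null places exactly 1/3 in each congruence class. The
closed-loop recovery experiment runs with `isoform_prob=0`: the
introns-only assembler emits one transcript per locus by construction, so
exact intron-level recovery is only a well-posed target against a
single-isoform truth; the isoform modes are exercised separately on
multi-isoform worlds.

## Known limitations

* No junction-spanning stop-codon check at chain time.
* No UTR or promoter/polyadenylation models; predictions are CDS-only.
* Partial genes at sequence edges are off by default
  (`allow_partial_genes`).
* The evidence bonus is soft: pathological score sums exceeding B could in
  principle override an evidence join (warned at run time).
* GFF3 `match_part` is the only alignment input dialect; PSL/SAM output of
  real aligners must be converted upstream.
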