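import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genechain.chainer import EvidenceIntron, GeneModelRules
from genechain.exon_builder import ExonCandidate
from genechain.formats_io import transcripts_from_features
from genechain.synthetic import SimConfig, simulate_ests, simulate_genome, train_from_truth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# shared synthetic world (session-scoped: simulation + training is not free)


@pytest.fixture(scope="session")
def sim_world():
    """A small simulated genome with truth, ESTs and trained parameters."""
    cfg = SimConfig(genome_length=30_000, n_genes=8, seed=1,
                    est_error_rate=0.0, isoform_prob=0.0,
                    est_len_range=(4000, 4000))
    genome, truth = simulate_genome(cfg)
    alignments = simulate_ests(genome, truth, cfg)
    params = train_from_truth(genome, truth)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "truth_tx": transcripts_from_features(truth),
        "alignments": alignments,
        "params": params,
    }


@pytest.fixture(scope="session")
def iso_world():
    """A simulated genome with exon-skipping isoforms and EST errors."""
    cfg = SimConfig(genome_length=40_000, n_genes=10, seed=5,
                    isoform_prob=0.6, est_error_rate=0.005,
                    est_len_range=(4000, 4000))
    genome, truth = simulate_genome(cfg)
    alignments = simulate_ests(genome, truth, cfg)
    params = train_from_truth(genome, truth)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "truth_tx": transcripts_from_features(truth),
        "alignments": alignments,
        "params": params,
    }


# ---------------------------------------------------------------------------
# random small chaining instances for DP-vs-oracle comparisons


CHAIN_RULES = GeneModelRules(
    min_intron_len=20, max_intron_len=300, min_intergenic=40,
    min_exon_len=5, max_exon_len=400,
)


def _mk(seqid, start, end, strand, klass, frame, score):
    return ExonCandidate(seqid=seqid, start=start, end=end, strand=strand,
                         exon_class=klass, frame=frame, score=score)


def random_chain_instance(rng: np.random.Generator, n_max: int = 15):
    """A random chaining instance: candidates + evidence introns + rules.

    Mixes structured material (frame-consistent backbones whose joins are
    feasible) with unstructured decoys, on both strands, so that optimal
    solutions range from empty to multi-gene.
    """
    rules = CHAIN_RULES
    seqid = "chr"
    candidates = []
    evidence = []
    pos = int(rng.integers(1, 60))
    n_backbones = int(rng.integers(1, 3))
    for _ in range(n_backbones):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        chain = []
        if n_ex == 1:
            length = int(rng.integers(6, 120))
            chain.append(("Single", pos, pos + length - 1, 0))
            pos += length
        else:
            frame = 0
            for k in range(n_ex):
                length = int(rng.integers(6, 120))
                if k == 0:
                    klass = "First" if strand == "+" else "Terminal"
                elif k == n_ex - 1:
                    klass = "Terminal" if strand == "+" else "First"
                else:
                    klass = "Internal"
                # transcript order differs from genomic order on '-': build
                # genomically left-to-right but chain frames accordingly
                chain.append([klass, pos, pos + length - 1, 0])
                pos += length
                if k < n_ex - 1:
                    pos += int(rng.integers(rules.min_intron_len,
                                            rules.max_intron_len // 2))
            # fix classes/frames for transcript orientation
            order = range(len(chain)) if strand == "+" else \
                range(len(chain) - 1, -1, -1)
            frame = 0
            for idx, k in enumerate(order):
                klass = ("First" if idx == 0 else
                         "Terminal" if idx == len(chain) - 1 else "Internal")
                chain[k][0] = klass
                chain[k][3] = frame
                length = chain[k][2] - chain[k][1] + 1
                frame = (3 - ((length - frame) % 3)) % 3
        for klass, s, e, f in [tuple(c) for c in chain]:
            candidates.append(
                _mk(seqid, s, e, strand, klass, f,
                    float(np.round(rng.normal(8, 8), 3)))
            )
        for k in range(len(chain) - 1):
            if rng.random() < 0.6:
                evidence.append(
                    EvidenceIntron(seqid, chain[k][2] + 1,
                                   chain[k + 1][1] - 1, strand)
                )
        pos += int(rng.integers(rules.min_intergenic + 1,
                                rules.min_intergenic + 150))

    # unstructured decoys
    n_decoys = int(rng.integers(0, max(2, n_max - len(candidates)) + 1))
    for _ in range(n_decoys):
        if len(candidates) >= n_max:
            break
        s = int(rng.integers(1, max(pos, 200)))
        length = int(rng.integers(5, 150))
        candidates.append(
            _mk(seqid, s, s + length - 1,
                "+" if rng.random() < 0.5 else "-",
                ["First", "Internal", "Terminal", "Single"][int(rng.integers(4))],
                int(rng.integers(3)),
                float(np.round(rng.normal(5, 10), 3)))
        )
    candidates = candidates[:n_max]
    # random junk evidence
    for _ in range(int(rng.integers(0, 3))):
        s = int(rng.integers(1, max(pos, 200)))
        ln = int(rng.integers(rules.min_intron_len, rules.max_intron_len))
        evidence.append(
            EvidenceIntron(seqid, s, s + ln - 1,
                           "+" if rng.random() < 0.5 else "-")
        )
    # normalize frames: First/Single must carry frame 0
    for c in candidates:
        if c.exon_class in ("First", "Single"):
            c.frame = 0
    return candidates, evidence, rules
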