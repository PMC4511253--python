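"""Seeded synthetic data with planted ground truth.

Functionally related genes tend to interact and organize into network
modules, so the benchmark plants modules: gene sets whose internal pairs are
emitted by each evidence source at an elevated rate, with raw scores drawn
from a higher range than background noise, and whose members preferentially
share annotation terms.  Half of module 1 serves as the reference set and
the other half as held-out positives, so end-to-end recovery of the held-out
members measures the whole pipeline without any external download.

All randomness flows from a single integer seed through spawned NumPy
generators; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .builders import BlastHit, ExpressionMatrix
from .netcore import AnnotationMap, EvidenceNetwork
from .prioritize import ReferenceGeneSet

#: raw-score ranges (before per-source scaling): overlapping uniforms so the
#: score bins are informative but imperfect.
TRUE_SCORE_RANGE = (0.5, 1.0)
NOISE_SCORE_RANGE = (0.0, 0.7)


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of the planted-module benchmark.

    Defaults define the standard study conditions: 500 genes, five planted
    modules of 20, within-module edge probability 0.3 against a 0.01
    background, three sources of decreasing reliability, and an 0.8 chance
    that two same-module genes share an annotation term.
    """

    n_genes: int = 500
    n_modules: int = 5
    module_size: int = 20
    p_within: float = 0.3
    p_between: float = 0.01
    n_sources: int = 3
    source_reliability: Tuple[float, ...] = (0.9, 0.7, 0.5)
    source_scales: Tuple[float, ...] = (1.0, 10.0, 100.0)
    annotation_terms: int = 50
    p_share_within: float = 0.8
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_between <= self.p_within <= 1.0:
            raise ValueError("need 0 <= p_between <= p_within <= 1")
        if self.module_size * self.n_modules > self.n_genes:
            raise ValueError("modules exceed the gene universe")
        if len(self.source_reliability) != self.n_sources:
            raise ValueError("one reliability per source required")
        if len(self.source_scales) != self.n_sources:
            raise ValueError("one scale per source required")
        if not all(0.0 <= p <= 1.0 for p in self.source_reliability):
            raise ValueError("reliabilities must lie in [0, 1]")


@dataclass
class BenchmarkBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    spec: BenchmarkSpec
    sources: List[EvidenceNetwork]
    ann: AnnotationMap
    refs: ReferenceGeneSet
    held_out_positives: Set[str]
    module_of: Dict[str, int]  # gene -> module index (0 = background)
    metadata: Dict[str, object] = field(default_factory=dict)


def _gene_ids(n: int) -> List[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_benchmark(spec: BenchmarkSpec) -> BenchmarkBundle:
    """Generate a full multi-source benchmark with planted modules.

    Per source k, a within-module pair is emitted with probability
    ``p_within * reliability[k]`` and scored from the true range; any other
    pair is emitted with ``p_between`` and scored from the noise range; both
    ranges are multiplied by the source's scale.  Annotations give every
    gene one term from a shared background pool and, with probability
    ``p_share_within``, its module's dedicated term.  The reference set is a
    random half of module 1; the held-out positives are the other half.
    """
    root = np.random.default_rng(spec.seed)
    rng_net, rng_ann, rng_ref = root.spawn(3)

    genes = _gene_ids(spec.n_genes)
    module_of = {g: 0 for g in genes}
    modules: List[List[str]] = []
    for m in range(spec.n_modules):
        block = genes[m * spec.module_size : (m + 1) * spec.module_size]
        modules.append(block)
        for g in block:
            module_of[g] = m + 1

    n = spec.n_genes
    iu, ju = np.triu_indices(n, k=1)
    mod_arr = np.array([module_of[g] for g in genes])
    within = (mod_arr[iu] == mod_arr[ju]) & (mod_arr[iu] > 0)

    sources: List[EvidenceNetwork] = []
    source_rngs = rng_net.spawn(spec.n_sources)
    for k in range(spec.n_sources):
        rng = source_rngs[k]
        rel = spec.source_reliability[k]
        scale = spec.source_scales[k]
        p_emit = np.where(within, spec.p_within * rel, spec.p_between)
        emitted = rng.random(len(iu)) < p_emit
        lo = np.where(within, TRUE_SCORE_RANGE[0], NOISE_SCORE_RANGE[0])
        hi = np.where(within, TRUE_SCORE_RANGE[1], NOISE_SCORE_RANGE[1])
        raw = rng.uniform(lo, hi) * scale
        net = EvidenceNetwork(source_id=f"source{k + 1}")
        for idx in np.flatnonzero(emitted):
            net.add_edge(genes[int(iu[idx])], genes[int(ju[idx])], float(raw[idx]))
        sources.append(net)

    ann: AnnotationMap = {}
    background_terms = [f"TERM:B{t:03d}" for t in range(spec.annotation_terms)]
    for g in genes:
        ann[g] = {background_terms[int(rng_ann.integers(spec.annotation_terms))]}
        m = module_of[g]
        if m > 0 and rng_ann.random() < spec.p_share_within:
            ann[g].add(f"TERM:M{m:02d}")

    module1 = list(modules[0])
    perm = rng_ref.permutation(len(module1))
    half = len(module1) // 2
    ref_genes = frozenset(module1[int(i)] for i in perm[:half])
    held_out = {module1[int(i)] for i in perm[half:]}

    return BenchmarkBundle(
        spec=spec,
        sources=sources,
        ann=ann,
        refs=ReferenceGeneSet(trait_label="planted-module-1", genes=ref_genes),
        held_out_positives=held_out,
        module_of=module_of,
        metadata={
            "true_score_range": TRUE_SCORE_RANGE,
            "noise_score_range": NOISE_SCORE_RANGE,
            "source_scales": list(spec.source_scales),
            "seed": spec.seed,
        },
    )


def simulate_expression(
    n_genes: int,
    n_samples: int,
    block: Sequence[str],
    block_correlation: float,
    seed: int,
    experiment_id: str = "sim-expr",
    genes: Optional[Sequence[str]] = None,
) -> ExpressionMatrix:
    """Expression matrix with one correlated gene block.

    Block genes follow a one-factor model, x = sqrt(rho) * f + sqrt(1 - rho)
    * eps with f and eps standard normal, so every within-block pair has
    expected Pearson correlation rho; all other genes are independent noise.
    """
    if not 0.0 <= block_correlation < 1.0:
        raise ValueError("block_correlation must lie in [0, 1)")
    if n_genes < 1 or n_samples < 2:
        raise ValueError("need n_genes >= 1 and n_samples >= 2")
    gene_ids = list(genes) if genes is not None else _gene_ids(n_genes)
    if len(gene_ids) != n_genes:
        raise ValueError("gene id list does not match n_genes")
    block_set = set(block)
    if not block_set <= set(gene_ids):
        raise ValueError("block genes must be a subset of the gene universe")
    rng = np.random.default_rng(seed)
    factor = rng.standard_normal(n_samples)
    values = rng.standard_normal((n_genes, n_samples))
    rho = block_correlation
    for i, g in enumerate(gene_ids):
        if g in block_set:
            values[i] = np.sqrt(rho) * factor + np.sqrt(1.0 - rho) * values[i]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(
        experiment_id=experiment_id, genes=gene_ids, samples=samples, values=values
    )


@dataclass
class BlastSim:
    """Simulated blastp table with pass/fail labels for every hit."""

    hits: List[BlastHit]
    query_lengths: Dict[str, int]
    true_pairs: Set[Tuple[str, str]]
    #: (query, subject) -> which single filter the decoy violates
    decoy_reason: Dict[Tuple[str, str], str]


def simulate_blast_hits(
    n_proteins: int,
    n_true_pairs: int,
    seed: int,
    n_decoys: Optional[int] = None,
) -> BlastSim:
    """Hit table where true pairs pass all three filters and each decoy
    violates exactly one (coverage, similarity, or e-value, cycled)."""
    if n_true_pairs + (n_decoys if n_decoys is not None else n_true_pairs) > (
        n_proteins * (n_proteins - 1) // 2
    ):
        raise ValueError("not enough protein pairs for the requested hits")
    if n_decoys is None:
        n_decoys = n_true_pairs
    rng = np.random.default_rng(seed)
    proteins = [f"p{i:04d}" for i in range(n_proteins)]
    lengths = {p: int(rng.integers(100, 1000)) for p in proteins}

    all_pairs = [(proteins[i], proteins[j]) for i in range(n_proteins) for j in range(i + 1, n_proteins)]
    picked = rng.choice(len(all_pairs), size=n_true_pairs + n_decoys, replace=False)
    hits: List[BlastHit] = []
    true_pairs: Set[Tuple[str, str]] = set()
    decoy_reason: Dict[Tuple[str, str], str] = {}

    def passing(q: str, s: str) -> BlastHit:
        qlen = lengths[q]
        return BlastHit(
            query=q,
            subject=s,
            pident=float(rng.uniform(45.0, 95.0)),
            align_len=int(rng.integers(int(np.ceil(0.5 * qlen)), qlen + 1)),
            evalue=float(10.0 ** rng.uniform(-50.0, -5.0)),
        )

    for rank, idx in enumerate(picked):
        q, s = all_pairs[int(idx)]
        hit = passing(q, s)
        if rank < n_true_pairs:
            true_pairs.add((q, s))
        else:
            reason = ("coverage", "similarity", "evalue")[(rank - n_true_pairs) % 3]
            if reason == "coverage":
                hit.align_len = max(1, int(0.5 * lengths[q]) - int(rng.integers(1, 40)))
            elif reason == "similarity":
                hit.pident = float(rng.uniform(5.0, 39.0))
            else:
                hit.evalue = float(10.0 ** rng.uniform(-3.9, -1.0))
            decoy_reason[(q, s)] = reason
        hits.append(hit)
    return BlastSim(
        hits=hits, query_lengths=lengths, true_pairs=true_pairs, decoy_reason=decoy_reason
    )
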