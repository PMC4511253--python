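"""Construct component evidence networks from raw data sources.

Five kinds of evidence feed the integrated network: interactions transferred
from donor-organism networks through ortholog pairs (interologs), coexpression
(Pearson r >= 0.7 over a combined expression matrix), curated PPI edge lists
(loaded directly by :func:`funlink.netcore.read_edge_list`), shared protein
domains, and sequence homology from filtered BLAST hits.  GO BP annotations
are likewise transferable to unannotated genes through orthology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .netcore import AnnotationMap, EvidenceNetwork, OrthologMap, ParseError

logger = logging.getLogger(__name__)

#: e-values of exactly 0 are clamped here so -log10 scores stay finite.
EVALUE_CLAMP = 1e-180


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one experiment (NaN = missing)."""

    experiment_id: str
    genes: List[str]
    samples: List[str]
    values: np.ndarray  # shape (len(genes), len(samples))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"{self.experiment_id}: value shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"{self.experiment_id}: duplicate gene ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class BlastHit:
    """One blastp hit (tabular outfmt 6 row); only the filter fields are used."""

    query: str
    subject: str
    pident: float
    align_len: int
    evalue: float

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise ValueError(f"align_len {self.align_len} < 1")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")


@dataclass
class DomainAssignment:
    """protein id -> non-empty set of functional-domain identifiers."""

    entries: Dict[str, Set[str]] = field(default_factory=dict)

    def add(self, protein: str, domain: str) -> None:
        self.entries.setdefault(protein, set()).add(domain)


# ---------------------------------------------------------------------------
# Readers for builder-specific formats.
# ---------------------------------------------------------------------------


def read_expression(path: Union[str, Path], experiment_id: str) -> ExpressionMatrix:
    """Read an expression TSV: header row of sample ids, first column gene id,
    missing values as "NA"."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], comment="#")
    return ExpressionMatrix(
        experiment_id=experiment_id,
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
    )


def read_blast_hits(path: Union[str, Path]) -> List[BlastHit]:
    """Read BLAST tabular outfmt 6 (12 standard tab-separated columns)."""
    hits: List[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: outfmt 6 needs 12 columns")
            try:
                hits.append(
                    BlastHit(
                        query=fields[0],
                        subject=fields[1],
                        pident=float(fields[2]),
                        align_len=int(fields[3]),
                        evalue=float(fields[10]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return hits


def read_query_lengths(path: Union[str, Path]) -> Dict[str, int]:
    """Read `protein<TAB>length` (amino acids)."""
    lengths: Dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected protein<TAB>length")
            try:
                lengths[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length") from None
    return lengths


def read_domain_assignments(path: Union[str, Path]) -> DomainAssignment:
    """Read `protein<TAB>domain_id` rows, aggregated per protein."""
    assign = DomainAssignment()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected protein<TAB>domain")
            assign.add(fields[0], fields[1])
    return assign


# ---------------------------------------------------------------------------
# Builders.
# ---------------------------------------------------------------------------


def combine_expression(
    experiments: Sequence[ExpressionMatrix],
    de_genes: Optional[Set[str]] = None,
    experiment_id: str = "combined",
) -> ExpressionMatrix:
    """Combine experiments into one consistent per-gene expression vector.

    Each gene row is z-scored within its experiment (removing platform scale
    differences), then rows are aligned by gene id and concatenated along the
    sample axis.  Genes absent from an experiment — or constant within it,
    hence not z-scorable — carry NaN in that block.  If ``de_genes`` is given
    only those genes are retained.
    """
    if not experiments:
        raise ValueError("at least one experiment required")
    blocks: List[pd.DataFrame] = []
    n_constant = 0
    for exp in experiments:
        df = exp.to_frame()
        if de_genes is not None:
            df = df.loc[df.index.intersection(sorted(de_genes))]
        mean = df.mean(axis=1)
        std = df.std(axis=1, ddof=0)
        constant = std == 0
        n_constant += int(constant.sum())
        z = df.sub(mean, axis=0).div(std.where(~constant), axis=0)
        z.columns = [f"{exp.experiment_id}:{s}" for s in df.columns]
        blocks.append(z)
    combined = pd.concat(blocks, axis=1, join="outer")
    combined = combined.loc[~combined.isna().all(axis=1)]
    combined = combined.sort_index()
    if combined.shape[0] == 0:
        raise ValueError("no usable genes after filtering")
    if n_constant:
        logger.info("combine_expression: %d constant gene block(s) set to missing", n_constant)
    return ExpressionMatrix(
        experiment_id=experiment_id,
        genes=[str(g) for g in combined.index],
        samples=[str(s) for s in combined.columns],
        values=combined.to_numpy(dtype=float),
    )


def build_coexpression(
    expr: ExpressionMatrix,
    threshold: float = 0.7,
    min_pairs: int = 3,
    source_id: str = "coexpression",
) -> EvidenceNetwork:
    """Coexpression network: edge iff Pearson r >= threshold (signed).

    Correlations use pairwise-complete observations and require at least
    ``min_pairs`` shared samples.  The correlation itself is the raw score,
    which doubles as the edge's confidence score.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    if len(expr.genes) < 2:
        raise ValueError("need at least 2 genes to correlate")
    df = expr.to_frame()
    corr = df.T.corr(method="pearson", min_periods=min_pairs)
    net = EvidenceNetwork(source_id=source_id)
    genes = list(corr.index)
    mat = corr.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.where(mat[iu, ju] >= threshold)[0]
    for idx in keep:
        i, j = int(iu[idx]), int(ju[idx])
        net.add_edge(genes[i], genes[j], float(mat[i, j]))
    logger.info(
        "build_coexpression: %d edges at r >= %g from %d genes", len(net), threshold, len(genes)
    )
    return net


def homology_score(evalue: float) -> float:
    """-log10 of the e-value; e-value 0 clamps to 1e-180 (score 180)."""
    return -math.log10(max(evalue, EVALUE_CLAMP))


def build_homology(
    hits: Iterable[BlastHit],
    query_lengths: Mapping[str, int],
    min_cov: float = 0.5,
    min_sim: float = 0.4,
    max_e: float = 1e-4,
    source_id: str = "homology",
) -> EvidenceNetwork:
    """Sequence-homology network from blastp hits.

    A hit survives iff alignment length >= ``min_cov`` of the query length,
    percent identity >= ``min_sim`` (as a fraction), and e-value < ``max_e``.
    The raw score is -log10(e-value); reciprocal hits collapse to one edge
    keeping the maximum score.
    """
    net = EvidenceNetwork(source_id=source_id)
    dropped = {"self": 0, "coverage": 0, "similarity": 0, "evalue": 0}
    for hit in hits:
        if hit.query not in query_lengths:
            raise KeyError(f"no query length for {hit.query!r}")
        if hit.query == hit.subject:
            dropped["self"] += 1
            continue
        if hit.align_len / query_lengths[hit.query] < min_cov:
            dropped["coverage"] += 1
            continue
        if hit.pident / 100.0 < min_sim:
            dropped["similarity"] += 1
            continue
        if not hit.evalue < max_e:
            dropped["evalue"] += 1
            continue
        net.add_edge(hit.query, hit.subject, homology_score(hit.evalue))
    logger.info("build_homology: %d edges kept; dropped %s", len(net), dropped)
    return net


def build_domain(assign: DomainAssignment, source_id: str = "domain") -> EvidenceNetwork:
    """Shared-domain network: edge per protein pair with >=1 common domain,
    scored by the number of shared domains."""
    net = EvidenceNetwork(source_id=source_id)
    by_domain: Dict[str, List[str]] = {}
    for protein, domains in assign.entries.items():
        if not domains:
            raise ValueError(f"protein {protein!r} listed with empty domain set")
        for d in domains:
            by_domain.setdefault(d, []).append(protein)
    pair_counts: Dict[Tuple[str, str], int] = {}
    for members in by_domain.values():
        members = sorted(members)
        for i, p in enumerate(members):
            for q in members[i + 1 :]:
                pair_counts[(p, q)] = pair_counts.get((p, q), 0) + 1
    for (p, q), n_shared in pair_counts.items():
        net.add_edge(p, q, float(n_shared))
    logger.info("build_domain: %d edges from %d domains", len(net), len(by_domain))
    return net


def build_interolog(
    donor_net: EvidenceNetwork,
    orth: OrthologMap,
    source_id: Optional[str] = None,
) -> EvidenceNetwork:
    """Transfer donor-organism interactions to the target genome (interologs).

    Every donor edge (A, B, s) yields a target edge (a, b, s) for every
    ortholog combination a of A, b of B with a != b; many-to-many groups
    enumerate all pairs.  Edges with an unmapped endpoint are skipped and
    duplicates keep the maximum transferred score.
    """
    mapping = orth.donor_to_targets()
    net = EvidenceNetwork(
        source_id=source_id or f"interolog:{orth.donor_organism}:{donor_net.source_id}"
    )
    n_unmapped = 0
    for a_donor, b_donor, score in donor_net.edges():
        targets_a = mapping.get(a_donor)
        targets_b = mapping.get(b_donor)
        if not targets_a or not targets_b:
            n_unmapped += 1
            continue
        for a in sorted(targets_a):
            for b in sorted(targets_b):
                if a != b:
                    net.add_edge(a, b, score)
    logger.info(
        "build_interolog[%s]: %d edges transferred, %d donor edges unmapped",
        net.source_id,
        len(net),
        n_unmapped,
    )
    return net


def transfer_annotations(
    ann: AnnotationMap,
    donor_anns: Sequence[Tuple[AnnotationMap, OrthologMap]],
    merge_annotated: bool = False,
) -> AnnotationMap:
    """Fill annotation gaps by orthology.

    Target genes absent from ``ann`` receive the union of their orthologs'
    terms across all donors; already-annotated genes are returned unchanged
    unless ``merge_annotated`` widens the rule to a union merge.
    """
    out: AnnotationMap = {g: set(terms) for g, terms in ann.items()}
    transferred: AnnotationMap = {}
    for donor_ann, omap in donor_anns:
        for target, donors in omap.target_to_donors().items():
            if target in ann and not merge_annotated:
                continue
            terms: Set[str] = set()
            for d in donors:
                terms |= donor_ann.get(d, set())
            if terms:
                transferred.setdefault(target, set()).update(terms)
    for gene, terms in transferred.items():
        out.setdefault(gene, set()).update(terms)
    logger.info("transfer_annotations: %d gene(s) gained annotations", len(transferred))
    return out
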