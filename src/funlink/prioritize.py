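"""Guilt-by-association gene prioritization.

Candidate genes for a trait are ranked by their connections to a reference
set — genes already associated with the trait.  The degree-of-association
score of gene i is the product of two sums over reference genes j directly
linked to i (excluding i itself):

    DAG_i = ( sum_j W_ij ) x ( sum_j P_ij )

with W_ij the integrated edge confidence and P_ij the 0/1 direct-link
indicator, so the second factor counts reference neighbors.  Scoring is
restricted by default to the reference subnet: the reference genes plus their
direct neighbors, with all edges among them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Set, Tuple

import pandas as pd

from .netcore import IntegratedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceGeneSet:
    """Genes previously associated with the trait under study."""

    trait_label: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.trait_label:
            raise ValueError("trait_label must be non-empty")
        if not self.genes:
            raise ValueError("reference gene set must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass
class PrioritizationResult:
    """Ranked per-gene scores.

    ``table`` columns: gene, dag, sum_w, n_ref_links, rank, is_reference;
    ranks run 1..G by descending dag with ties broken by gene id.
    """

    trait_label: str
    scope: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def scores(self) -> pd.Series:
        return self.table.set_index("gene")["dag"]

    def __len__(self) -> int:
        return len(self.table)


def extract_reference_subnet(
    net: IntegratedNetwork, refs: ReferenceGeneSet
) -> IntegratedNetwork:
    """Induced subnetwork on the reference genes plus their direct neighbors.

    Keeps every edge with at least one reference endpoint and every edge
    among the retained nodes.  Reference ids absent from the network are
    logged; if none is present the neighborhood is undefined and an error is
    raised.
    """
    nodes = net.nodes()
    present = refs.genes & nodes
    missing = refs.genes - nodes
    if missing:
        logger.warning(
            "%d reference gene(s) absent from network: %s",
            len(missing),
            ", ".join(sorted(missing)[:10]),
        )
    if not present:
        raise ValueError(f"no reference gene of {refs.trait_label!r} appears in the network")
    keep = set(present)
    for u, v, _r, _src in net.edges():
        if u in present:
            keep.add(v)
        if v in present:
            keep.add(u)
    sub = IntegratedNetwork()
    for u, v, r, src in net.edges():
        if u in keep and v in keep:
            sub.add_edge(u, v, r, src)
    return sub


def dag_score(
    net: IntegratedNetwork, refs: ReferenceGeneSet, gene: str
) -> Tuple[float, float, int]:
    """Degree of association of one gene: (dag, sum_w, n_ref_links).

    sum_w sums the edge confidences from ``gene`` to its reference
    neighbors, n_ref_links counts them, and dag is their product.  The
    gene's own reference membership contributes nothing (i = j excluded).
    """
    adj = net.adjacency()
    if gene not in adj and gene not in net.nodes():
        raise KeyError(f"gene {gene!r} not in network")
    return _dag_from_adjacency(adj.get(gene, {}), refs.genes, gene)


def _dag_from_adjacency(
    neighbor_weights: dict, ref_genes: frozenset, gene: str
) -> Tuple[float, float, int]:
    sum_w = 0.0
    n_links = 0
    # sorted iteration fixes the float summation order (canonical edge order)
    for j in sorted(neighbor_weights):
        if j in ref_genes and j != gene:
            sum_w += neighbor_weights[j]
            n_links += 1
    return sum_w * n_links, sum_w, n_links


def prioritize(
    net: IntegratedNetwork,
    refs: ReferenceGeneSet,
    scope: str = "subnet",
) -> PrioritizationResult:
    """Score and rank every gene in scope by its degree of association.

    ``scope="subnet"`` (default) scores the reference subnet only, matching
    the extraction step of the method; ``scope="all"`` scores every network
    gene (genes with no reference neighbor keep score 0).  Genes absent from
    the network are absent from the output.
    """
    if scope == "subnet":
        scored_net = extract_reference_subnet(net, refs)
    elif scope == "all":
        if not (refs.genes & net.nodes()):
            raise ValueError(
                f"no reference gene of {refs.trait_label!r} appears in the network"
            )
        scored_net = net
    else:
        raise ValueError(f"unknown scope {scope!r}")
    adj = scored_net.adjacency()
    rows = []
    for gene in sorted(scored_net.nodes()):
        dag, sum_w, n_links = _dag_from_adjacency(adj.get(gene, {}), refs.genes, gene)
        rows.append(
            {
                "gene": gene,
                "dag": dag,
                "sum_w": sum_w,
                "n_ref_links": n_links,
                "is_reference": gene in refs.genes,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "dag", "sum_w", "n_ref_links", "is_reference"])
    table = table.sort_values(["dag", "gene"], ascending=[False, True], kind="mergesort")
    table["rank"] = range(1, len(table) + 1)
    table = table[["gene", "dag", "sum_w", "n_ref_links", "rank", "is_reference"]]
    table = table.reset_index(drop=True)
    logger.info("prioritize[%s]: scored %d genes", scope, len(table))
    return PrioritizationResult(trait_label=refs.trait_label, scope=scope, table=table)


def write_ranking(result: PrioritizationResult, path, header_comments=()) -> None:
    """Write the ranked table as TSV (full-precision scores)."""
    with open(path, "w", encoding="utf-8") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("gene\tdag\tsum_w\tn_ref_links\trank\tis_reference\n")
        for row in result.table.itertuples(index=False):
            fh.write(
                f"{row.gene}\t{row.dag!r}\t{row.sum_w!r}\t{row.n_ref_links}\t"
                f"{row.rank}\t{int(row.is_reference)}\n"
            )


def read_ranking(path, trait_label: str = "trait", scope: str = "subnet") -> PrioritizationResult:
    """Read a ranked TSV written by :func:`write_ranking`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["is_reference"] = df["is_reference"].astype(bool)
    return PrioritizationResult(trait_label=trait_label, scope=scope, table=df)
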