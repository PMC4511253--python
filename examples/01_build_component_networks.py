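"""Build each kind of component evidence network from raw inputs.

Every evidence source becomes an EvidenceNetwork: an undirected gene graph
with a raw score per edge, on whatever scale that source produces.
"""

from funlink import (
    DomainAssignment,
    OrthologMap,
    EvidenceNetwork,
    build_coexpression,
    build_domain,
    build_homology,
    build_interolog,
)
from funlink.simdata import simulate_blast_hits, simulate_expression

# Coexpression: 30 genes, an 8-gene correlated block (factor model, r ~ 0.9).
block = [f"g{i:04d}" for i in range(8)]
expr = simulate_expression(30, 100, block, block_correlation=0.9, seed=8)
coexpr = build_coexpression(expr, threshold=0.7)
within = sum(1 for u, v, _ in coexpr.edges() if u in block and v in block)
print(f"coexpression: {len(coexpr)} edges at r >= 0.7, {within} inside the planted block")

# Homology: 5 hits passing all three BLAST filters, 5 decoys failing one each.
sim = simulate_blast_hits(n_proteins=40, n_true_pairs=5, seed=6, n_decoys=5)
homology = build_homology(sim.hits, sim.query_lengths)
print(f"homology: {len(homology)} of {len(sim.hits)} hits kept "
      f"(scores are -log10 e-value, e.g. {next(iter(homology.scores())):.1f})")

# Shared domains: the score is the number of domains two proteins share.
assign = DomainAssignment({"p1": {"PF01", "PF02", "PF03"}, "p2": {"PF02", "PF03"},
                           "p3": {"PF03"}})
domain = build_domain(assign)
for u, v, s in domain.edges():
    print(f"domain: {u}--{v} share {s:.0f} domain(s)")

# Interologs: donor-organism interactions mapped through ortholog pairs.
donor = EvidenceNetwork(source_id="donor-net")
donor.add_edge("H1", "H2", 0.9)
orth = OrthologMap("donor", {("H1", "b1"), ("H1", "b1_paralog"), ("H2", "b2")})
interolog = build_interolog(donor, orth)
print(f"interolog: {len(interolog)} edges transferred "
      "(one donor edge, two orthologs of H1)")
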