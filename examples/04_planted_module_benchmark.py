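"""End-to-end planted-module recovery on synthetic data.

Generates three evidence sources over 500 genes with five planted 20-gene
modules, calibrates and integrates them, then asks whether the held-out
half of module 1 is recovered when the other half serves as the reference
set.  An AUC near 1 means the pipeline concentrates confidence on real
module structure; the no-signal configuration stays near 0.5.
"""

from funlink import (
    BenchmarkSpec,
    ReferenceGeneSet,
    confidence_table,
    integrate,
    prioritize,
    roc_auc,
    simulate_benchmark,
)

for label, spec in [
    ("default benchmark", BenchmarkSpec(seed=42)),
    ("no-signal control", BenchmarkSpec(seed=42, p_within=0.02, p_between=0.02,
                                        source_reliability=(1.0, 1.0, 1.0))),
]:
    bundle = simulate_benchmark(spec)
    table = confidence_table(bundle.sources, bundle.ann)
    net = integrate(bundle.sources, table)
    result = prioritize(net, bundle.refs, scope="all")
    held = ReferenceGeneSet("held-out", frozenset(bundle.held_out_positives))
    ev = roc_auc(result, held, loo=False)
    print(f"{label}: {len(net)} integrated edges over {len(net.nodes())} genes, "
          f"held-out recovery AUC = {ev.auc:.3f}")
print("The default run should print an AUC above 0.9; the control, near 0.5.")
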