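"""Integrate differential-expression calls across datasets.

Builds eight synthetic DEG tables sharing a 120-gene core plus one
"spoiler" dataset that shares almost nothing, filters them at
|log2FC| >= 1 and p < 0.05, and lets progressive elimination find the
dataset subset with the largest common-gene intersection.
"""

from n4 import deg_integration as deg
from n4.synthio import SynthConfig, make_deg_tables

cfg = SynthConfig(seed=1, deg_spoiler_core=5)
tables, truth = make_deg_tables(cfg)

trace, gene_sets = deg.integrate(tables, min_datasets=8)

print("datasets in:", len(tables))
print("intersection of all datasets:",
      len(deg.intersect(list(gene_sets.values()))), "genes")
for removed, size in trace.steps:
    print(f"  removed {removed:>12s} -> intersection grows to {size}")
print("final:", len(trace.final_genes), "genes shared by",
      len(trace.final_datasets), "datasets")

# The spoiler dataset shares only 5 core genes, so keeping it caps the
# common set at 5; removing it first recovers the full 120-gene core.
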