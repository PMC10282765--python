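"""Gene-set cross-referencing, Fisher enrichment, and 2^-ddCt.

Intersects a "nitrogen-responsive" list with a "yield-associated" list
(Venn selection), tests the overlap with Fisher's exact test, tabulates
a catalogue into major/minor classes, and computes a qPCR fold change.
"""

import pandas as pd

from n4 import genesets as gs

n_resp = gs.GeneSet("n_responsive", {f"g{i:04d}" for i in range(0, 300)})
yield_assoc = gs.GeneSet("yield", {f"g{i:04d}" for i in range(250, 420)})

regions = gs.venn([n_resp, yield_assoc])
print({sig: len(members) for sig, members in regions.items()})

universe = {f"g{i:04d}" for i in range(1000)}
res = gs.enrichment(n_resp, yield_assoc, universe=universe)
print(f"2x2 = [{res.a},{res.b},{res.c},{res.d}] "
      f"odds ratio {res.odds_ratio:.2f}, two-sided p {res.p_two_sided:.3g}")

catalogue = pd.DataFrame(
    [{"gene_id": f"g{i:04d}", "category": f"TF_class_{i % 5}"} for i in range(40)]
)
table = gs.crosstab(n_resp, catalogue, major_min=3)
print(f"{table.n_classes} classes: {table.n_major_classes} major "
      f"({table.major_gene_total} genes), {table.n_minor_classes} minor "
      f"({table.minor_gene_total} genes)")

meas = gs.QPCRMeasurement(
    ct={"test": {"target": 23.1, "reference": 19.8},
        "control": {"target": 25.4, "reference": 20.0}}
)
print(f"fold change = {gs.relative_expression(meas):.2f}")

# The "11" Venn region (here 50 genes) is the candidate set that is both
# N-responsive and yield-associated; the Fisher p says whether that
# overlap exceeds chance against the declared universe; a fold change
# > 1 means the target is up-regulated in the test condition after
# normalizing to the reference gene.
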