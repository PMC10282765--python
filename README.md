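# n4 — nitrogen-responsive gene meta-analysis

`n4` is a desk-scale, fully testable re-implementation of a common
systems-biology workflow for dissecting crop nitrogen-use efficiency
(NUE) at the gene level: integrate differential-expression calls from
many transcriptome datasets, find co-expressed gene modules linked to
sample traits, rank hub genes on a protein-interaction network, scan
gene sequences for putative G-quadruplex (G4) motifs, and cross-
reference the resulting gene sets against annotation catalogues.

Every stage is an importable library module; a thin `n4` command wraps
them, and a synthetic-data generator produces inputs with *known planted
structure* so the whole pipeline runs — and can be scored — without any
external database.

## The methods in brief

- **DEG integration.** Per-dataset tables (gene, log2FC, p) are filtered
  at |log2FC| ≥ 1 and p < 0.05 (duplicate probes collapsed by max
  |log2FC|). Because one sparse dataset can collapse the common-gene
  intersection, datasets are *eliminated progressively*: greedily drop
  the dataset whose removal most enlarges the intersection of the rest,
  reporting the full k-vs-intersection trade-off curve.
- **Weighted co-expression network.** Adjacency
  a<sub>ij</sub> = |cor(x<sub>i</sub>, x<sub>j</sub>)|<sup>β</sup>
  (signed variant available); β is the smallest power whose connectivity
  distribution fits a scale-free topology (R² of log p(k) vs log k above
  a target, negative slope). Topological overlap
  TOM<sub>ij</sub> = (l<sub>ij</sub> + a<sub>ij</sub>) /
  (min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>) with
  l<sub>ij</sub> = Σ<sub>u</sub> a<sub>iu</sub>a<sub>uj</sub>; modules
  come from average-linkage clustering of 1 − TOM with a static cut,
  labeled largest-first (turquoise, blue, brown, …), merged when their
  eigengenes correlate above 0.75.
- **Module–trait statistics.** Each module's eigengene (first principal
  component of its standardized expression) is correlated with numeric
  sample traits (Student-t p, BH-adjusted). A module is *significant*
  when its best trait relation has r² > 0.5 **and** module membership
  (gene–eigengene correlation) tracks gene significance (|gene–trait
  correlation|) within the module.
- **Hub genes.** On a thresholded interaction network, Maximal Clique
  Centrality MCC(v) = Σ<sub>cliques C ∋ v</sub> (|C|−1)! ranks hubs;
  MCODE-style k-core-seeded expansion extracts dense clusters.
- **G-quadruplex scanning.** De novo matches of
  G<sub>m</sub>N<sub>1–7</sub>G<sub>m</sub>N<sub>1–7</sub>G<sub>m</sub>N<sub>1–7</sub>G<sub>m</sub>
  with m = 2 (G2) or 3 (G3) on both strands, annotated with every gene
  region they overlap (promoter / 5'UTR / CDS / exon / 3'UTR / gene) and
  summarized per gene, region, strand and module.
- **Gene sets.** Exact Venn selection, Fisher's exact test (two-sided,
  point-probability rule, Haldane-corrected odds ratios), major/minor
  catalogue cross-tabulation, and 2<sup>−ΔΔCt</sup> relative expression
  for qPCR validation.

## Worked example

```sh
n4 run --demo --seed 1 --out demo_out
```

generates all inputs synthetically and runs every stage. The summary it
writes (`demo_out/summary.txt`):

```
n4 pipeline report (seed 1, config 604ab6c6c0d52565)
shared genes after elimination: 120 from 8 datasets
soft threshold beta = 9 (scale-free R^2 = 0.6292786640532045)
module sizes: turquoise=30, blue=24
significant modules: turquoise
top hub genes: gene0001, gene0003, gene0004, gene0006, gene0008, gene0009, gene0016, gene0018, gene0011, gene0013
G4: 14 hits in 14 genes; per region {'promoter': 3, '5utr': 3, 'exon': 11, 'cds': 6, '3utr': 2, 'gene': 11}
shared-genes x G4 venn: {'11': 9, '10': 111, '01': 5}
```

Reading this: the eight generated datasets share a planted 120-gene
core, which the elimination stage recovers exactly. Clustering the
topological overlap of those genes yields two modules (the third planted
module is only partially sampled by the shared core and falls below the
20-gene minimum); the largest is labeled turquoise and is the one whose
eigengene tracks the planted age trait strongly enough (r² > 0.5) to be
called significant. Hub genes are ranked on an interaction network
generated over the turquoise genes with two planted cliques. All 14
planted G4 motifs are found at their planted coordinates — none in the
quadruplex-free background — and 9 of the G4-containing genes are also
in the shared set (the "11" Venn region).

The `examples/` directory has one short narrative script per
capability (DEG integration, co-expression + modules, hub ranking, G4
scanning, gene-set statistics, full pipeline).

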