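# Methods

## Scope and design

`n4` implements a multi-stage meta-analysis of nitrogen-responsive gene
expression: dataset integration, weighted co-expression network
analysis, hub-gene detection, G-quadruplex scanning, and gene-set
statistics. The stages are independent library modules composed by
`n4.pipeline`. All heavy numerics are dense and desk-scale (thousands of
genes, not tens of thousands); there is no block-wise or approximate
mode.

External resources (expression repositories, interaction databases,
quadruplex databases) are deliberately out of scope: expression
matrices, DEG tables, edge lists, sequences and catalogues are plain
files the user supplies. The synthetic generator (`n4.synthio`) stands
in for those resources during testing.

## DEG integration

A record passes when |log2FC| ≥ `fc_threshold` (default 1.0; the
absolute value admits down-regulated genes — an `fc_mode="up"` switch
restricts to up-regulation) and p < `p_threshold` (default 0.05,
strict). Duplicate gene ids (multiple probes) are collapsed before
thresholding, keeping the record with maximal |log2FC|, ties to the
smaller p, then first occurrence; this makes filtering invariant to
record order and to a global sign flip.

"Progressive elimination" is formalized as a greedy leave-one-out loop:
at each step remove the dataset whose removal maximizes the intersection
of the remainder; ties go to the dataset with the smallest own gene set,
then lexicographic id; stop at `min_datasets`. The trace is monotone by
construction and the k-vs-intersection curve is returned so users can
pick the knee themselves. Greedy is not optimal in general (removals
interact through overlapping "blocked" gene sets); the tests prove
equality with exhaustive subset search on instances whose blocked sets
are disjoint — where greedy is provably optimal — and bound it by the
exhaustive optimum elsewhere. Only single-dataset removals are
considered per step.

## Co-expression network

Pearson correlation of expression profiles, raised to the soft power β:
unsigned a = |r|^β (default) or signed a = ((1+r)/2)^β. Missing values
and constant genes are hard errors (keeping the oracles exact) rather
than pairwise-complete fallbacks.

Scale-free fit: connectivities k_i = Σ_{j≠i} a_ij are binned into
`n_bins` (default 10) equal-width bins; within nonempty bins, log10 of
the mean connectivity is regressed against log10 of the bin's relative
frequency; the fit's squared correlation is the R². Fewer than three
nonempty bins is an undefined fit. β is selected as the smallest
candidate with R² ≥ `r2_target` (default 0.9) and negative slope; if no
candidate qualifies the β with maximal R² is returned, flagged
`fallback` in the screening table. On small synthetic matrices R²
rarely reaches 0.9 — the fallback is the common path there and is
reported as such, never silently.

TOM uses the canonical unsigned formula
TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with the diagonal
excluded from l and k and TOM_ii = 1. The implementation is one matrix
product; an O(n³) scalar loop serves as the oracle in tests (agreement
to 1e-12 at n ≤ 30).

## Module detection and statistics

Average-linkage hierarchical clustering of d = 1 − TOM with a *static*
height cut (deterministic and oracle-checkable, unlike dynamic hybrid
cutting). The default cut is 0.9 × the highest merge height: after
soft-threshold sparsification the dissimilarities between unrelated
genes concentrate immediately below 1, so the top of the tree is a
plateau of uninformative merges and a near-maximal cut factor would
absorb background genes into modules; 0.9 sits below that plateau
across the noise range the generator covers (residual SD 0.1–0.5) while
leaving planted modules intact. `cut_height` is exposed for data where
this heuristic fails. Clusters under `min_module_size` (default 20)
are grey (unassigned); the rest are labeled by size rank through the
conventional color order (turquoise, blue, brown, …), so "turquoise"
always denotes the largest module.

Eigengenes are the first right-singular vector of the per-gene
standardized module submatrix, sign-oriented to correlate positively
with the module's mean profile; `var_explained` is the first squared
singular value over the total. Modules merge iteratively while the
closest eigengene pair has dissimilarity 1 − cor < `merge_threshold`
(default 0.25); the larger constituent keeps its label and eigengenes
are recomputed after each merge, making the operation idempotent.

Module–trait relationships are Pearson correlations of eigengene vs
numeric trait with two-sided p from the Student-t transform
t = r√(n−2)/√(1−r²) and BH adjustment across the whole module × trait
grid. Gene significance is the *unsigned* |cor(gene, trait)|; module
membership is cor(gene, eigengene). A module is significant when
max-over-traits r² exceeds `r2_cut` (default 0.5; a `mtr_as_r` switch
reads the cut on |r| instead, since "R² > 0.5" is ambiguous in common
usage) and the |MM|–GS correlation within the module is significant at
`p_cut` for the best trait.

## Hub detection

Edge lists are thresholded at load (default score ≥ 0.4, the usual
medium-confidence convention); topology is unweighted afterwards.
MCC(v) = Σ (|C|−1)! over maximal cliques C containing v, enumerated by
networkx's pivoting Bron–Kerbosch; isolated nodes score 0. Node counts
above 5000 are refused (clique enumeration is exponential in the worst
case) with guidance to threshold harder or restrict to a module.
Dense clusters follow the MCODE recipe with its default parameters
(node weight percentage 0.2, k-core ≥ 2): each node is weighted by the
highest core number of its closed neighborhood's densest k-core times
that core's density, clusters grow from the highest-weight unvisited
seed admitting neighbors within the weight cutoff, and clusters of ≥ 3
nodes are reported sorted by density × size.

## G-quadruplex scanning

The scanner implements the canonical quadruplex-forming pattern family
G{m,}(N{1,7}G{m,}){3} with m = 2 (subtype G2) and m = 3 (G3), leftmost
non-overlapping matching for countable deterministic hits. The minus
strand is scanned on the reverse complement with coordinates mapped
back. With `subtype="both"` a locus takes its maximal subtype: every G3
locus also matches the G2 pattern (nesting), and is reported once, as
G3. Region annotation attaches every label whose span the hit overlaps
by ≥ 1 bp; the promoter is `promoter_len` bp (default 1000) upstream of
the transcription start on the gene's strand. Region summaries count
*genes* (once per region with ≥ 1 hit), not hits. Strand bias is
(plus − minus)/minus × 100. Coordinates are 0-based half-open
throughout; BED12 is native, GFF3 is converted on read. No
thermodynamic stability scoring (G4Hunter-style) is attempted.

## Gene-set statistics

Venn selection enumerates all 2ⁿ−1 membership signatures with exact
member sets. Fisher's exact test is two-sided by the point-probability
rule — sum hypergeometric probabilities of all same-margin tables whose
probability is ≤ the observed table's, with a 1e-7 relative tolerance
on the comparison (a mid-p variant is available); the odds ratio is
ad/bc with Haldane's 0.5 correction when any cell is zero. The
enrichment universe must be declared by the caller; the default (union
of the input sets) is conservative and explicit in the output. BH
adjustment applies across one batch of tests. Catalogue cross-tabulation
counts a gene once per category it carries (the unique-gene total is
reported separately) and splits classes at `major_min` (default 3).
2^−ΔΔCt averages replicate CTs per (group, gene) first, then
ΔΔCt = (Ct_tgt,test − Ct_ref,test) − (Ct_tgt,ctrl − Ct_ref,ctrl); the
result is invariant under any constant CT shift.

## The synthetic generator

One integer seed drives every generator through independent
per-operation substreams, so outputs are byte-identical across runs and
each generator is reproducible in isolation.

*Expression.* K planted modules (defaults: sizes 50/40/30 in a 200-gene
universe, 40 samples — array-scale numbers kept desk-sized) follow a
latent-factor model x_g = λ_g f_m + ε with loadings λ ~ U[0.6, 1] and
ε ~ N(0, σ), σ = 0.3 by default (a realistic residual-to-signal ratio
for curated microarray compendia). In the σ = 0 limit genes are exact
multiples of their factor, giving rank-K structure and eigengene =
factor. Remaining genes are i.i.d. noise. Traits are linear in their
mapped module's factor with the residual orthogonalized so the
*in-sample* correlation equals the target exactly; defaults map plant
age (days) at r = −0.8, N dose at r = −0.75, and tissue at r = 0.8 —
strengths chosen so that, as in real N-response compendia, at least one
module passes the r² > 0.5 significance gate. Tissue is emitted both as
a categorical column (root/shoot/whole, by terciles of its latent) and
as its integer coding; discretization attenuates its realized
correlation below the target.

*DEG tables.* Each of 8 datasets carries the same 120-gene core (spread
evenly across the universe so the shared set samples every module plus
background, as shared DEGs do across real arrays), 20 private passing
genes, and 10 decoys failing exactly one threshold. An optional spoiler
dataset shares only a few core genes, exercising elimination.

*Sequences.* One chromosome per gene with a fixed layout (1 kb
promoter, 200 bp 5'UTR, 600 bp CDS, 200 bp 3'UTR, single exon; mirrored
for minus-strand genes). The background never contains two consecutive
identical G or C characters, hence no quadruplex match on either
strand; planted motifs (A/T loops, G2 runs pinned to length 2 so
subtypes are unambiguous) are the only hits, with flanks sanitized so
runs cannot extend. Scanner recall and precision against the plant
ledger are therefore exactly 100% by construction.

*Networks.* Disjoint planted cliques (sizes 6 and 5 by default, scores
in (0.5, 1]) over a sparse background (density 0.02, scores ≤ 0.5).

What the generator does **not** emulate: probe-level noise, batch
effects, normalization artifacts, correlated background genes,
overlapping gene models, multi-exon transcripts, or realistic genomic
G/C composition. Passing the planted-recovery tests shows the
algorithms are correct on data satisfying their assumptions, not that
real microarray compendia satisfy them.

## Numerical choices

Correlations are clipped to [−1, 1] before powering; TOM is clipped to
[0, 1] after division. Dissimilarity matrices are symmetrized
((d + dᵀ)/2) before linkage to absorb floating-point asymmetry.
Eigengene sign ties (profile orthogonal to the mean profile) keep the
SVD's sign. Tie-breaks everywhere are deterministic and documented at
the operation (elimination: smallest set then id; hub ranking: degree
then id; merging: larger module keeps the label, alphabetical on size
ties). Degenerate inputs (constant genes, zero-variance traits, < 3
nonempty histogram bins, modules of < 2 genes) raise or flag NA rather
than propagating NaNs.

## Problem sizes

The test-suite and acceptance runs use 200-gene / 40-sample expression
matrices, ≤ 12-node graphs for exhaustive oracles, 1000 permutations for
calibration, and 10–20 generator seeds per recovery experiment — sizes
at which every independent oracle (O(n³) TOM loop, 2ⁿ subset
enumeration, full contingency enumeration, exhaustive subset search)
runs exactly, keeping every comparison bit-honest rather than sampled.

Planted-module recovery (adjusted Rand index) is scored over the genes
the generator assigned to modules; background noise genes are excluded
from the comparison. A noise gene whose random profile happens to
correlate with a factor in-sample *is* co-expressed in the realized
data, so penalizing its assignment would score the data, not the
algorithm. The exact-size recovery checks use a background-free
fixture for the same reason.

## Known limitations

- The static tree cut is a single global height; modules at very
  different tightness scales need manual `cut_height` tuning where a
  dynamic cut would adapt.
- Greedy elimination can be suboptimal when datasets' missing-gene sets
  overlap heavily; the emitted trade-off curve makes this visible but
  does not repair it.
- Scale-free R² on small dense matrices is noisy; β selection then
  falls back to the max-R² candidate and says so.
- The G4 scanner is purely pattern-based; it neither scores stability
  nor handles RNA folding, and non-overlapping counting undercounts
  overlapping quadruplex arrangements (an overlapping mode exists for
  enumeration but not for the summaries).
- Fisher enumeration is exact but O(min margin); it is meant for
  gene-set-scale tables, not millions of tests.
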