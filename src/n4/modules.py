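"""Co-expression module detection and module-trait statistics.

Genes are clustered by average-linkage hierarchical clustering on the
topological-overlap dissimilarity 1 - TOM and a static cut of the tree
yields modules; clusters smaller than the minimum module size fall into
the unassigned "grey" bin.  Modules are labeled by size rank through the
conventional color list (turquoise for the largest, then blue, brown,
...).  Each module is summarized by its eigengene — the first principal
component of the module's standardized expression — and modules whose
eigengenes are nearly collinear are merged.  Module relevance to sample
traits is scored two ways: (i) the module-trait relationship, the Pearson
correlation between eigengene and trait with a Student-t p-value and BH
adjustment across the module x trait grid; (ii) the within-module
association between module membership (gene-eigengene correlation, MM)
and gene significance (absolute gene-trait correlation, GS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

GREY = "grey"

# WGCNA-style color order, largest module first; overflow gets numbered labels
COLOR_ORDER = [
    "turquoise", "blue", "brown", "yellow", "green", "black", "red", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def module_label(rank: int) -> str:
    """Label for the rank-th largest module (rank 0 = largest)."""
    if rank < len(COLOR_ORDER):
        return COLOR_ORDER[rank]
    return f"module_{rank + 1:02d}"


@dataclass
class ModuleAssignment:
    labels: dict[str, str]  # gene_id -> module label ("grey" = unassigned)
    min_module_size: int
    cut_height: float

    def members(self, label: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == label]

    def module_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for m in self.labels.values():
            sizes[m] = sizes.get(m, 0) + 1
        return sizes

    def non_grey(self) -> list[str]:
        sizes = self.module_sizes()
        return sorted((m for m in sizes if m != GREY), key=lambda m: (-sizes[m], m))


def detect_modules(
    dissimilarity: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 20,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    ``cut_height`` defaults to 0.9 x the highest merge in the tree:
    soft-thresholded TOM dissimilarities concentrate close to 1 for
    unrelated genes, so the informative merges sit well below the top of
    the tree.  Clusters below ``min_module_size`` become grey; the rest
    are labeled largest-first along the fixed color order.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be a symmetric square matrix")
    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    link = hierarchy.linkage(squareform(dsym, checks=False), method="average")
    max_height = float(link[-1, 2])
    if cut_height is None:
        cut_height = 0.9 * max_height
    if not 0.0 < cut_height <= max_height:
        raise ValueError(
            f"cut_height must lie in (0, {max_height:.6g}], got {cut_height}"
        )
    flat = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    labels: dict[str, str] = {}
    clusters: dict[int, list[str]] = {}
    for g, c in zip(gene_ids, flat):
        clusters.setdefault(int(c), []).append(g)
    kept = [m for m in clusters.values() if len(m) >= min_module_size]
    kept.sort(key=lambda m: (-len(m), m[0]))
    for rank, members in enumerate(kept):
        for g in members:
            labels[g] = module_label(rank)
    for g in gene_ids:
        labels.setdefault(g, GREY)
    return ModuleAssignment(labels=labels, min_module_size=min_module_size, cut_height=float(cut_height))


def eigengene(expr_sub: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First principal component of a module's standardized expression.

    Genes (rows) are standardized to mean 0 / SD 1 across samples; the
    eigengene is the first right-singular vector over samples, sign-
    oriented to correlate positively with the module's mean profile.
    Returns ``(profile, var_explained)`` with the profile unit-norm.
    """
    x = expr_sub.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("module must contain at least 2 genes")
    if x.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant gene {expr_sub.index[flat[0]]!r} in module")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    profile = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    if profile @ mean_profile < 0:
        profile = -profile
    return profile, var_explained


@dataclass
class ModuleEigengenes:
    profiles: dict[str, np.ndarray]
    var_explained: dict[str, float]
    sample_ids: list[str] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {m: p for m, p in self.profiles.items()},
            index=self.sample_ids or None,
        ).T


def module_eigengenes(expr: pd.DataFrame, assignment: ModuleAssignment) -> ModuleEigengenes:
    profiles, var = {}, {}
    for m in assignment.non_grey():
        prof, ve = eigengene(expr.loc[assignment.members(m)])
        profiles[m] = prof
        var[m] = ve
    return ModuleEigengenes(profiles=profiles, var_explained=var, sample_ids=list(expr.columns))


def merge_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    merge_threshold: float = 0.25,
) -> tuple[ModuleAssignment, ModuleEigengenes]:
    """Merge modules whose eigengene dissimilarity 1 - cor(ME_i, ME_j) < threshold.

    Iterative closest-pair merging; the merged module keeps the larger
    constituent's label and its eigengene is recomputed after each merge.
    """
    labels = dict(assignment.labels)
    while True:
        current = ModuleAssignment(labels, assignment.min_module_size, assignment.cut_height)
        mods = current.non_grey()
        if len(mods) < 2:
            break
        eg = module_eigengenes(expr, current)
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = float(np.corrcoef(eg.profiles[mods[i]], eg.profiles[mods[j]])[0, 1])
                diss = 1.0 - r
                if diss < merge_threshold and (best is None or diss < best[0]):
                    best = (diss, mods[i], mods[j])
        if best is None:
            break
        _, a, b = best
        sizes = current.module_sizes()
        # larger constituent keeps its label; size ties go alphabetically
        if sizes[a] > sizes[b] or (sizes[a] == sizes[b] and a < b):
            keep, drop = a, b
        else:
            keep, drop = b, a
        for g, m in labels.items():
            if m == drop:
                labels[g] = keep
    merged = ModuleAssignment(labels, assignment.min_module_size, assignment.cut_height)
    return merged, module_eigengenes(expr, merged)


def relabel_by_size(assignment: ModuleAssignment) -> ModuleAssignment:
    """Re-apply the size-ordered color convention (e.g. after merging)."""
    sizes = assignment.module_sizes()
    order = sorted((m for m in sizes if m != GREY), key=lambda m: (-sizes[m], m))
    mapping = {m: module_label(i) for i, m in enumerate(order)}
    mapping[GREY] = GREY
    return ModuleAssignment(
        {g: mapping[m] for g, m in assignment.labels.items()},
        assignment.min_module_size,
        assignment.cut_height,
    )


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via the Student-t transform."""
    if n < 3:
        raise ValueError("need n >= 3")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_relationships(
    eigengenes: ModuleEigengenes, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r, p, and BH q per (module, trait) pair.

    Non-numeric trait columns are ignored; zero-variance traits are
    reported with NA statistics and excluded from the BH adjustment.
    """
    numeric = traits.select_dtypes(include=[np.number])
    rows = []
    for m, profile in eigengenes.profiles.items():
        n = len(profile)
        for trait in numeric.columns:
            y = numeric[trait].to_numpy(dtype=float)
            if np.std(y) == 0 or n < 3:
                rows.append({"module": m, "trait": trait, "r": np.nan, "p": np.nan})
                continue
            r = float(np.corrcoef(profile, y)[0, 1])
            rows.append({"module": m, "trait": trait, "r": r, "p": correlation_pvalue(r, n)})
    mtr = pd.DataFrame(rows)
    mtr["q"] = np.nan
    ok = mtr["p"].notna()
    if ok.any():
        mtr.loc[ok, "q"] = multipletests(mtr.loc[ok, "p"], method="fdr_bh")[1]
    return mtr


def gene_module_stats(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    eigengenes: ModuleEigengenes,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene module membership (MM) and gene significance (GS) per trait."""
    numeric = traits.select_dtypes(include=[np.number])
    rows = []
    for m in assignment.non_grey():
        me = eigengenes.profiles[m]
        for g in assignment.members(m):
            x = expr.loc[g].to_numpy(dtype=float)
            row = {"gene_id": g, "module": m, "MM": float(np.corrcoef(x, me)[0, 1])}
            for trait in numeric.columns:
                y = numeric[trait].to_numpy(dtype=float)
                row[f"GS_{trait}"] = (
                    float(abs(np.corrcoef(x, y)[0, 1])) if np.std(y) > 0 else np.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def significant_modules(
    mtr: pd.DataFrame,
    gene_stats: pd.DataFrame,
    r2_cut: float = 0.5,
    p_cut: float = 0.05,
    mtr_as_r: bool = False,
) -> pd.DataFrame:
    """Modules passing both trait-relation and MM-GS coherence criteria.

    A module qualifies when (max over traits of r^2) > ``r2_cut`` (or
    |r| > r2_cut with ``mtr_as_r``) and the correlation between module
    membership and gene significance for the best trait is significant at
    ``p_cut``.  Returns one row per qualifying module, strongest MM-GS
    association first.
    """
    rows = []
    for m, sub in mtr.dropna(subset=["r"]).groupby("module"):
        strength = sub["r"].abs() if mtr_as_r else sub["r"] ** 2
        best = sub.loc[strength.idxmax()]
        best_strength = abs(best["r"]) if mtr_as_r else best["r"] ** 2
        if best_strength <= r2_cut:
            continue
        genes = gene_stats[gene_stats["module"] == m]
        if len(genes) < 3:
            continue
        gs_col = f"GS_{best['trait']}"
        mm = genes["MM"].abs().to_numpy()
        gs = genes[gs_col].to_numpy(dtype=float)
        if np.std(mm) == 0 or np.std(gs) == 0:
            continue
        r_mmgs = float(np.corrcoef(mm, gs)[0, 1])
        p_mmgs = correlation_pvalue(r_mmgs, len(genes))
        if p_mmgs < p_cut:
            rows.append(
                {
                    "module": m,
                    "best_trait": best["trait"],
                    "mtr_r": float(best["r"]),
                    "mm_gs_r": r_mmgs,
                    "mm_gs_p": p_mmgs,
                }
            )
    out = pd.DataFrame(rows, columns=["module", "best_trait", "mtr_r", "mm_gs_r", "mm_gs_p"])
    return out.sort_values("mm_gs_r", ascending=False, key=np.abs).reset_index(drop=True)
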