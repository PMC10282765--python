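"""Weighted co-expression network construction.

The network is built from pairwise Pearson correlation of expression
profiles, raised elementwise to a soft-threshold power beta:

* unsigned:  a_ij = |cor(x_i, x_j)|^beta
* signed:    a_ij = ((1 + cor(x_i, x_j)) / 2)^beta

beta is chosen as the smallest candidate whose network approximates a
scale-free topology: the connectivity distribution p(k) is binned and
log10 p(k) regressed on log10 k; the fit R^2 must reach a target (default
0.9) with negative slope.  The topological overlap matrix then measures
shared-neighbor similarity,

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   i != j,

with l_ij = sum_u a_iu a_uj over u distinct from i and j, k_i the
connectivity of i excluding the diagonal, and TOM_ii = 1.  The clustering
dissimilarity downstream is 1 - TOM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoexpressionNetwork:
    gene_ids: list[str]
    adjacency: np.ndarray
    beta: int
    network_type: str
    tom: np.ndarray | None = None

    @property
    def connectivity(self) -> np.ndarray:
        a = self.adjacency.copy()
        np.fill_diagonal(a, 0.0)
        return a.sum(axis=1)

    def dissimilarity(self) -> np.ndarray:
        if self.tom is None:
            raise ValueError("TOM not computed; call tom_matrix first")
        return 1.0 - self.tom


def _correlation(expr: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if np.isnan(expr).any():
        raise ValueError("missing values in expression are not supported")
    sd = expr.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant expression for gene {gene_ids[flat[0]]!r}")
    c = np.corrcoef(expr)
    return np.clip(c, -1.0, 1.0)


def adjacency_matrix(
    expr: pd.DataFrame, beta: int = 6, network_type: str = "unsigned"
) -> CoexpressionNetwork:
    """Soft-thresholded adjacency from a genes x samples expression frame."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if network_type not in ("unsigned", "signed"):
        raise ValueError(f"unknown network_type {network_type!r}")
    gene_ids = list(expr.index)
    c = _correlation(expr.to_numpy(dtype=float), gene_ids)
    if network_type == "unsigned":
        a = np.abs(c) ** beta
    else:
        a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return CoexpressionNetwork(gene_ids=gene_ids, adjacency=a, beta=int(beta), network_type=network_type)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    """Goodness of scale-free topology: R^2 of log p(k) vs log k.

    Connectivities are binned into ``n_bins`` equal-width bins; within each
    nonempty bin the mean connectivity is the abscissa and the bin's
    relative frequency the ordinate, both log10-transformed.  Returns
    ``(r2, slope, mean_k)``.
    """
    k = np.asarray(connectivity, dtype=float)
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if (k < 0).any():
        raise ValueError("connectivity must be nonnegative")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        mean_k_bin = k[mask].mean()
        freq = n / k.size
        if mean_k_bin <= 0:
            continue
        xs.append(np.log10(mean_k_bin))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        raise ValueError(
            f"scale-free fit undefined: only {len(xs)} nonempty bins (need >= 3)"
        )
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r), float(slope), float(k.mean())


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_betas: list[int] | None = None,
    r2_target: float = 0.9,
    network_type: str = "unsigned",
    n_bins: int = 10,
) -> tuple[int | None, pd.DataFrame]:
    """Screen candidate powers; pick the smallest with r2 >= target and slope < 0.

    If no candidate qualifies, the beta with maximal r2 is returned and the
    screening table's ``selected`` column flags it with ``fallback``.
    Returns ``(beta, table)``; beta is None only if every fit failed.
    """
    if candidate_betas is None:
        candidate_betas = list(range(1, 13)) + [14, 16, 18, 20]
    if not candidate_betas:
        raise ValueError("candidate_betas must be nonempty")
    rows = []
    for beta in sorted(candidate_betas):
        net = adjacency_matrix(expr, beta=beta, network_type=network_type)
        try:
            r2, slope, mean_k = scale_free_fit(net.connectivity, n_bins=n_bins)
        except ValueError:
            rows.append({"beta": beta, "r2": np.nan, "slope": np.nan, "mean_k": np.nan})
            continue
        rows.append({"beta": beta, "r2": r2, "slope": slope, "mean_k": mean_k})
    table = pd.DataFrame(rows)
    table["selected"] = ""
    ok = table.dropna(subset=["r2"])
    qualifying = ok[(ok["r2"] >= r2_target) & (ok["slope"] < 0)]
    if len(qualifying):
        beta = int(qualifying.iloc[0]["beta"])
        table.loc[table["beta"] == beta, "selected"] = "selected"
    elif len(ok):
        beta = int(ok.loc[ok["r2"].idxmax(), "beta"])
        table.loc[table["beta"] == beta, "selected"] = "fallback"
    else:
        beta = None
    return beta, table


def tom_matrix(net: CoexpressionNetwork) -> CoexpressionNetwork:
    """Topological overlap of the adjacency; fills ``net.tom`` and returns it."""
    a = np.array(net.adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be a symmetric square matrix")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # l_ij = sum_u a_iu a_uj; diagonal terms vanish since a_ii = 0
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    net.tom = np.clip(tom, 0.0, 1.0)
    return net


def build_network(
    expr: pd.DataFrame,
    beta: int | None = None,
    network_type: str = "unsigned",
    r2_target: float = 0.9,
    candidate_betas: list[int] | None = None,
) -> tuple[CoexpressionNetwork, pd.DataFrame | None]:
    """Convenience: pick beta if not given, then adjacency + TOM."""
    table = None
    if beta is None:
        beta, table = pick_soft_threshold(
            expr, candidate_betas, r2_target=r2_target, network_type=network_type
        )
        if beta is None:
            raise ValueError("soft-threshold selection failed for every candidate")
    net = adjacency_matrix(expr, beta=beta, network_type=network_type)
    tom_matrix(net)
    return net, table
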