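"""Gene-set algebra, enrichment, catalogue cross-tabulation, and qPCR.

Covers the "Venn selection" style of analysis — exact intersections of
gene lists with all 2^n - 1 membership signatures — plus Fisher's exact
test for 2x2 enrichment (two-sided by the point-probability rule, with
Haldane-corrected odds ratios), cross-tabulation of a query gene set
against a gene -> category catalogue with a major/minor class split, and
the 2^-ddCt relative-expression computation for qPCR cycle thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSet:
    name: str
    members: set[str]
    universe_size: int | None = None

    def __post_init__(self):
        self.members = set(self.members)
        if self.universe_size is not None and self.universe_size < len(self.members):
            raise ValueError(
                f"set {self.name!r} has {len(self.members)} members but a "
                f"declared universe of {self.universe_size}"
            )


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """One gene id per line; '#' lines and blanks ignored."""
    path = Path(path)
    members = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                members.add(line)
    return GeneSet(name=name or path.stem, members=members)


def venn(sets: list[GeneSet]) -> dict[str, set[str]]:
    """Exact member sets for every nonempty membership signature.

    Signature "101" = in set 1, not set 2, in set 3 (order of input).
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    universe = set().union(*(s.members for s in sets))
    out: dict[str, set[str]] = {}
    for bits in product("10", repeat=len(sets)):
        sig = "".join(bits)
        if sig == "0" * len(sets):
            continue
        region = set(universe)
        for bit, s in zip(bits, sets):
            region &= s.members if bit == "1" else (universe - s.members)
        out[sig] = region
    return out


def overlap_percent(query: GeneSet, reference: GeneSet) -> tuple[int, float]:
    """Size and percentage of ``query`` members found in ``reference``."""
    if not query.members:
        raise ValueError("empty query set")
    n = len(query.members & reference.members)
    return n, 100.0 * n / len(query.members)


@dataclass
class EnrichmentResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    q: float | None = None


def fisher_exact(a: int, b: int, c: int, d: int, mid_p: bool = False) -> EnrichmentResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    p sums the hypergeometric probabilities of all tables with the same
    margins whose point probability does not exceed the observed one
    (with a 1e-7 relative tolerance on the comparison).  The odds ratio
    is ad/bc with a Haldane 0.5 correction when any cell is zero.
    ``mid_p`` halves the observed table's own contribution.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be nonnegative")
    n = sum(cells)
    if n == 0:
        raise ValueError("empty contingency table")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = float(hypergeom.pmf(a, n, col1, row1))
    keep = pmf <= p_obs * (1.0 + 1e-7)
    p = float(pmf[keep].sum())
    if mid_p:
        p -= 0.5 * p_obs
    p = min(1.0, max(p, 0.0))
    if min(cells) == 0:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    return EnrichmentResult(a=a, b=b, c=c, d=d, odds_ratio=(a_ * d_) / (b_ * c_), p_two_sided=p)


def enrichment(
    query: GeneSet,
    annotation: GeneSet,
    universe: set[str] | None = None,
) -> EnrichmentResult:
    """Is ``annotation`` over-represented in ``query`` against ``universe``?

    The universe defaults to the union of both sets; supply the true
    background explicitly whenever it is known.
    """
    if universe is None:
        universe = query.members | annotation.members
    q = query.members & universe
    t = annotation.members & universe
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(universe) - a - b - c
    return fisher_exact(a, b, c, d)


def adjust_enrichments(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """BH adjustment across one batch of enrichment tests (in place)."""
    if not results:
        return results
    qs = multipletests([r.p_two_sided for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


@dataclass
class CategoryTable:
    counts: pd.DataFrame  # category, n_genes, split
    major_min: int
    n_major_classes: int
    n_minor_classes: int
    major_gene_total: int
    minor_gene_total: int
    unique_genes: int
    per_module: pd.DataFrame | None = None

    @property
    def n_classes(self) -> int:
        return self.n_major_classes + self.n_minor_classes

    @property
    def gene_total(self) -> int:
        """Category-count total (a gene in two categories counts twice)."""
        return self.major_gene_total + self.minor_gene_total


def read_catalogue(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene_id", "category"} <= set(df.columns):
        raise ValueError(f"{path}: catalogue needs gene_id and category columns")
    return df


def crosstab(
    query: GeneSet,
    catalogue: pd.DataFrame,
    major_min: int = 3,
    modules: dict[str, str] | None = None,
) -> CategoryTable:
    """Category counts of a catalogue restricted to a query gene set.

    Classes with >= ``major_min`` genes are "major", the rest "minor";
    a gene annotated to several categories counts once in each, while
    ``unique_genes`` counts it once overall.
    """
    if catalogue.empty:
        raise ValueError("empty catalogue")
    sub = catalogue[catalogue["gene_id"].isin(query.members)].drop_duplicates(
        ["gene_id", "category"]
    )
    counts = (
        sub.groupby("category")["gene_id"].nunique().sort_values(ascending=False)
    )
    frame = counts.reset_index().rename(columns={"gene_id": "n_genes"})
    frame["split"] = np.where(frame["n_genes"] >= major_min, "major", "minor")
    major = frame[frame["split"] == "major"]
    minor = frame[frame["split"] == "minor"]
    per_module = None
    if modules is not None:
        sub2 = sub.assign(module=sub["gene_id"].map(modules))
        per_module = (
            sub2.dropna(subset=["module"])
            .groupby("module")["gene_id"]
            .nunique()
            .sort_values(ascending=False)
            .reset_index()
            .rename(columns={"gene_id": "n_genes"})
        )
    return CategoryTable(
        counts=frame,
        major_min=major_min,
        n_major_classes=len(major),
        n_minor_classes=len(minor),
        major_gene_total=int(major["n_genes"].sum()),
        minor_gene_total=int(minor["n_genes"].sum()),
        unique_genes=int(sub["gene_id"].nunique()),
        per_module=per_module,
    )


@dataclass
class QPCRMeasurement:
    """Mean cycle thresholds per (group, gene); replicates pre-averaged.

    ``ct[group][gene]`` with groups 'test'/'control' and genes
    'target'/'reference'.
    """

    ct: dict[str, dict[str, float]]

    @classmethod
    def from_replicates(cls, table: pd.DataFrame) -> "QPCRMeasurement":
        """From a long table (group, gene, replicate, ct)."""
        need = {"group", "gene", "ct"}
        if not need <= set(table.columns):
            raise ValueError(f"CT table needs columns {sorted(need)}")
        ct: dict[str, dict[str, float]] = {}
        for (group, gene), sub in table.groupby(["group", "gene"]):
            ct.setdefault(group, {})[gene] = float(sub["ct"].mean())
        return cls(ct=ct)


def relative_expression(meas: QPCRMeasurement) -> float:
    """Fold change by the 2^-ddCt method.

    ddCt = (Ct_target,test - Ct_ref,test) - (Ct_target,control - Ct_ref,control).
    """
    for group in ("test", "control"):
        if group not in meas.ct:
            raise ValueError(f"missing group {group!r}")
        for gene in ("target", "reference"):
            if gene not in meas.ct[group]:
                raise ValueError(f"missing gene {gene!r} in group {group!r}")
        if any(v <= 0 for v in meas.ct[group].values()):
            raise ValueError("CT values must be positive")
    d_test = meas.ct["test"]["target"] - meas.ct["test"]["reference"]
    d_ctrl = meas.ct["control"]["target"] - meas.ct["control"]["reference"]
    return float(2.0 ** (-(d_test - d_ctrl)))


def write_venn(regions: dict[str, set[str]], path: str | Path) -> None:
    rows = [
        {"signature": sig, "n_genes": len(g), "genes": ",".join(sorted(g))}
        for sig, g in sorted(regions.items())
    ]
    pd.DataFrame(rows, columns=["signature", "n_genes", "genes"]).to_csv(
        path, sep="\t", index=False
    )
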