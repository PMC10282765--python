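"""Multi-dataset differential-expression integration.

Filters per-dataset DEG tables by uniform |log2FC| and p-value thresholds
(collapsing redundant probes per gene), intersects the surviving gene
sets, and — because a single sparse dataset can collapse the common-gene
intersection — finds a well-shared dataset subset by greedy progressive
elimination: at each step drop the dataset whose removal most enlarges
the intersection of the remainder, until a minimum number of datasets is
left.  The full trace (dataset removed, intersection size after) is
returned so the number of retained datasets can be chosen from the
k-vs-intersection trade-off curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ("gene_id", "log2fc", "pvalue")


@dataclass
class EliminationTrace:
    """Record of one progressive-elimination run."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    final_datasets: set[str] = field(default_factory=set)
    final_genes: set[str] = field(default_factory=set)

    @property
    def curve(self) -> list[tuple[int, int]]:
        """(number of datasets remaining, intersection size) per step."""
        n0 = len(self.final_datasets) + len(self.steps)
        return [(n0 - i - 1, size) for i, (_, size) in enumerate(self.steps)]


def read_deg_table(path: str | Path, dataset_id: str | None = None) -> pd.DataFrame:
    """Read a DEG TSV (gene_id, log2fc, pvalue); '#' lines are comments."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[df["gene_id"].isna() | (df["gene_id"].astype(str) == "")]
    if len(bad):
        raise ValueError(f"{path}: empty gene_id at data line {bad[0] + 2}")
    for col in ("log2fc", "pvalue"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at data line {bad[0] + 2}")
        df[col] = vals
    if ((df["pvalue"] < 0) | (df["pvalue"] > 1)).any():
        raise ValueError(f"{path}: p-value outside [0, 1]")
    df.attrs["dataset_id"] = dataset_id or path.stem
    return df


def collapse_redundant(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene_ids, keeping the record with max |log2fc|.

    Ties go to the smaller p-value, then to the first occurrence.
    """
    df = table.copy()
    df["_absfc"] = df["log2fc"].abs()
    df["_order"] = range(len(df))
    df = df.sort_values(
        ["_absfc", "pvalue", "_order"], ascending=[False, True, True], kind="stable"
    )
    df = df.drop_duplicates("gene_id", keep="first").sort_values("_order")
    return df.drop(columns=["_absfc", "_order"]).reset_index(drop=True)


def filter_degs(
    table: pd.DataFrame,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fc_mode: str = "abs",
) -> set[str]:
    """Gene ids passing |log2FC| >= fc_threshold and p < p_threshold.

    ``fc_mode='up'`` restricts to up-regulated genes (log2FC >= threshold
    without the absolute value); ``'abs'`` is the default reading.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if fc_mode not in ("abs", "up"):
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    if len(table) == 0:
        return set()
    df = collapse_redundant(table)
    fc = df["log2fc"].abs() if fc_mode == "abs" else df["log2fc"]
    keep = (fc >= fc_threshold) & (df["pvalue"] < p_threshold)
    return set(df.loc[keep, "gene_id"])


def intersect(sets: list[set[str]]) -> set[str]:
    """Exact intersection of one or more gene-id sets."""
    if not sets:
        raise ValueError("need at least one set")
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def progressive_elimination(
    gene_sets: dict[str, set[str]], min_datasets: int
) -> EliminationTrace:
    """Greedy leave-one-out maximization of the common-gene intersection.

    At each step the dataset whose removal maximizes the intersection of
    the remainder is dropped (ties: smallest own gene set, then
    lexicographic dataset id) until ``min_datasets`` remain.
    """
    if not 2 <= min_datasets <= len(gene_sets):
        raise ValueError(
            f"min_datasets must be in [2, {len(gene_sets)}], got {min_datasets}"
        )
    remaining = dict(gene_sets)
    trace = EliminationTrace()
    while len(remaining) > min_datasets:
        best = None
        for ds in remaining:
            others = [s for d, s in remaining.items() if d != ds]
            size = len(intersect(others))
            key = (-size, len(remaining[ds]), ds)
            if best is None or key < best[0]:
                best = (key, ds, size)
        _, ds, size = best
        del remaining[ds]
        trace.steps.append((ds, size))
    trace.final_datasets = set(remaining)
    trace.final_genes = intersect(list(remaining.values())) if remaining else set()
    return trace


def integrate(
    tables: list[pd.DataFrame],
    min_datasets: int,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    fc_mode: str = "abs",
) -> tuple[EliminationTrace, dict[str, set[str]]]:
    """Filter every table and run progressive elimination."""
    gene_sets = {
        t.attrs.get("dataset_id", f"ds{i:02d}"): filter_degs(
            t, fc_threshold, p_threshold, fc_mode
        )
        for i, t in enumerate(tables)
    }
    return progressive_elimination(gene_sets, min_datasets), gene_sets


def write_trace(trace: EliminationTrace, path: str | Path) -> None:
    rows = [
        {"step": i + 1, "removed_dataset": ds, "intersection_after": size}
        for i, (ds, size) in enumerate(trace.steps)
    ]
    pd.DataFrame(rows, columns=["step", "removed_dataset", "intersection_after"]).to_csv(
        path, sep="\t", index=False
    )


def write_gene_list(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")
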