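"""Synthetic inputs with planted, scoreable structure.

Every generator is driven by a single integer seed and returns, alongside
the data, a ground-truth ledger sufficient to score the downstream stage
that consumes it: planted module membership and latent factors for the
co-expression stages, the core/private/decoy composition of each
differential-expression table, planted G-quadruplex coordinates for the
scanner, and clique membership for the hub stage.

The expression model is a latent-factor model: each planted module ``m``
has one latent factor ``f_m`` (one value per sample, standard normal), and
a member gene ``g`` is generated as ``x_g = lam_g * f_m + eps`` with
loading ``lam_g ~ U[0.6, 1.0]`` and ``eps ~ N(0, module_noise_sd)``.  In
the noise-free limit the module eigengene coincides with the latent
factor, which gives closed-form recovery checks.  Traits are noisy linear
functions of their mapped module's factor, tuned to a target Pearson
correlation.

Sequences are built so the background is quadruplex-free on *both*
strands: the background generator never emits two identical consecutive
G or C characters, so any G-run (or, on the reverse complement, C-run) of
length >= 2 comes from a planted motif.  Scanner recall and precision
against the plant ledger are therefore exact by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

REGION_LABELS = ("promoter", "5utr", "cds", "exon", "3utr")

# fixed per-chromosome layout (coordinates 0-based half-open)
_CHROM_LEN = 2100
_PLUS_LAYOUT = {
    "promoter": (0, 1000),
    "gene": (1000, 2000),
    "exon": (1000, 2000),
    "5utr": (1000, 1200),
    "cds": (1200, 1800),
    "3utr": (1800, 2000),
}
_MINUS_LAYOUT = {
    "promoter": (1100, 2100),
    "gene": (100, 1100),
    "exon": (100, 1100),
    "5utr": (900, 1100),
    "cds": (300, 900),
    "3utr": (100, 300),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SynthConfig:
    """Knobs for every synthetic input, all fed by one seed.

    ``trait_module_map`` maps a trait name to ``(module_index, target_r)``;
    the trait named ``tissue`` is additionally emitted as a categorical
    column (root/shoot/whole) next to its integer coding.
    """

    seed: int = 0
    n_genes: int = 200
    n_samples: int = 40
    module_sizes: tuple[int, ...] = (50, 40, 30)
    module_noise_sd: float = 0.3
    trait_module_map: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {
            "age_days": (0, -0.8),
            "n_dose": (1, -0.75),
            "tissue": (2, 0.8),
        }
    )
    n_datasets: int = 8
    deg_overlap_core: int = 120
    deg_private_per_dataset: int = 20
    deg_decoys_per_dataset: int = 10
    deg_spoiler_core: int | None = None
    g4_plant_spec: tuple[tuple[str, str, int], ...] = (
        ("promoter", "G3", 3),
        ("5utr", "G2", 3),
        ("cds", "G3", 4),
        ("exon", "G2", 2),
        ("3utr", "G2", 2),
    )
    clique_sizes: tuple[int, ...] = (6, 5)
    network_background_nodes: int = 20
    network_background_density: float = 0.02

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate_expression(self) -> None:
        if self.module_noise_sd < 0:
            raise ValueError("module_noise_sd must be nonnegative")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        for trait, (m, r) in self.trait_module_map.items():
            if not 0 <= m < self.n_modules:
                raise ValueError(f"trait {trait!r} maps to unknown module {m}")
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"trait {trait!r} target correlation {r} outside [-1, 1]")

    def validate_deg(self) -> None:
        if self.deg_overlap_core + self.deg_private_per_dataset > self.n_genes:
            raise ValueError("DEG core + private genes exceed the gene universe")

    def validate_sequences(self) -> None:
        for region, subtype, count in self.g4_plant_spec:
            if region not in REGION_LABELS:
                raise ValueError(f"unknown region label {region!r}")
            if subtype not in ("G2", "G3"):
                raise ValueError(f"unknown G4 subtype {subtype!r}")
            if count < 0:
                raise ValueError("plant count must be nonnegative")

    def validate(self) -> None:
        self.validate_expression()
        self.validate_deg()
        self.validate_sequences()

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"gene{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def _rng(self, stream: int) -> np.random.Generator:
        # one generator per operation, all derived from the single seed
        return np.random.default_rng([int(self.seed), stream])


def make_expression(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a genes x samples expression matrix plus a sample-trait table.

    Returns ``(expr, traits, ledger)`` where the ledger records planted
    module membership, the latent factors, and each trait's target
    correlation.
    """
    config.validate_expression()
    rng = config._rng(1)
    genes = config.gene_ids()
    samples = [f"S{j:03d}" for j in range(1, config.n_samples + 1)]

    factors = rng.standard_normal((config.n_modules, config.n_samples))
    factors = (factors - factors.mean(axis=1, keepdims=True)) / factors.std(axis=1, keepdims=True)

    expr = np.empty((config.n_genes, config.n_samples))
    membership: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(config.module_sizes):
        lam = rng.uniform(0.6, 1.0, size=size)
        noise = rng.normal(0.0, config.module_noise_sd, size=(size, config.n_samples))
        expr[pos : pos + size] = lam[:, None] * factors[m][None, :] + noise
        for g in genes[pos : pos + size]:
            membership[g] = m
        pos += size
    n_background = config.n_genes - pos
    if n_background:
        expr[pos:] = rng.standard_normal((n_background, config.n_samples))
        for g in genes[pos:]:
            membership[g] = -1

    traits = pd.DataFrame(index=pd.Index(samples, name="sample"))
    for trait, (m, r) in config.trait_module_map.items():
        eps = rng.standard_normal(config.n_samples)
        eps = (eps - eps.mean()) / eps.std()
        # residualize so the achieved in-sample correlation matches the target
        eps = eps - factors[m] * (eps @ factors[m]) / (factors[m] @ factors[m])
        eps /= eps.std()
        latent = r * factors[m] + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        if trait == "tissue":
            codes = np.digitize(latent, np.quantile(latent, [1 / 3, 2 / 3]))
            traits["tissue"] = np.array(["root", "shoot", "whole"])[codes]
            traits["tissue_code"] = codes
        else:
            scale = {"age_days": (21.0, 7.0), "n_dose": (8.0, 6.0)}.get(trait, (0.0, 1.0))
            traits[trait] = scale[0] + scale[1] * latent

    expr_df = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    ledger = {
        "module_of_gene": membership,
        "latent_factors": factors.tolist(),
        "trait_targets": {t: {"module": m, "r": r} for t, (m, r) in config.trait_module_map.items()},
    }
    return expr_df, traits, ledger


def make_deg_tables(config: SynthConfig) -> tuple[list[pd.DataFrame], dict]:
    """Per-dataset differential-expression tables with a known core.

    Every regular dataset contains the same ``deg_overlap_core`` core genes
    passing |log2FC| >= 1 and p < 0.05, plus dataset-private passing genes
    and decoy rows failing exactly one threshold.  If
    ``deg_spoiler_core`` is set, one extra "spoiler" dataset is appended
    sharing only that many core genes (to exercise progressive
    elimination).
    """
    config.validate_deg()
    rng = config._rng(2)
    genes = config.gene_ids()
    # core genes spread evenly across the universe so they sample every
    # planted module plus background, as shared DEGs do in real arrays
    idx = np.unique(
        np.round(np.linspace(0, config.n_genes - 1, config.deg_overlap_core)).astype(int)
    )
    core = [genes[i] for i in idx]

    def passing(rng, n):
        fc = rng.uniform(1.0, 4.0, n) * rng.choice([-1.0, 1.0], n)
        p = rng.uniform(1e-8, 0.049, n)
        return fc, p

    tables: list[pd.DataFrame] = []
    private_of: dict[str, list[str]] = {}
    pool = [g for g in genes if g not in set(core)]
    for d in range(config.n_datasets):
        ds = f"ds{d + 1:02d}"
        private = list(
            rng.choice(pool, size=min(config.deg_private_per_dataset, len(pool)), replace=False)
        )
        private_of[ds] = private
        rows = []
        fc, p = passing(rng, len(core) + len(private))
        for g, f_, p_ in zip(core + private, fc, p):
            rows.append((g, f_, p_))
        # decoys: fail exactly one of the two thresholds
        decoy_genes = rng.choice(pool, size=config.deg_decoys_per_dataset, replace=False)
        for i, g in enumerate(decoy_genes):
            if i % 2 == 0:
                rows.append((g, rng.uniform(-0.9, 0.9), rng.uniform(1e-6, 0.049)))
            else:
                rows.append((g, rng.uniform(1.0, 4.0), rng.uniform(0.05, 1.0)))
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue"])
        df.attrs["dataset_id"] = ds
        tables.append(df)

    if config.deg_spoiler_core is not None:
        shared = core[: config.deg_spoiler_core]
        fc, p = passing(rng, len(shared))
        df = pd.DataFrame(zip(shared, fc, p), columns=["gene_id", "log2fc", "pvalue"])
        df.attrs["dataset_id"] = "ds_spoiler"
        tables.append(df)

    ledger = {
        "core_genes": core,
        "private_genes": private_of,
        "spoiler": "ds_spoiler" if config.deg_spoiler_core is not None else None,
    }
    return tables, ledger


def _background_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Sequence over {A,C,G,T} with no two consecutive identical G or C.

    No GG run on the plus strand and no CC run (= GG on the minus strand),
    so the background matches no G-quadruplex pattern on either strand.
    """
    alphabet = np.array(list("ACGT"))
    seq = rng.choice(alphabet, size=length)
    for i in range(1, length):
        if seq[i] == seq[i - 1] and seq[i] in ("G", "C"):
            seq[i] = rng.choice(["A", "T"])
    return seq


def _motif(rng: np.random.Generator, subtype: str) -> str:
    """A canonical quadruplex motif: four G-runs with short A/T loops."""
    # G2 runs stay at exactly 2 so a planted G2 motif can never be read as G3
    if subtype == "G3":
        runs = ["G" * int(rng.integers(3, 5)) for _ in range(4)]
    else:
        runs = ["GG"] * 4
    loops = [
        "".join(rng.choice(["A", "T"], size=int(rng.integers(1, 8)))) for _ in range(3)
    ]
    out = runs[0]
    for loop, run in zip(loops, runs[1:]):
        out += loop + run
    return out


def make_sequences(
    config: SynthConfig,
) -> tuple[dict[str, str], pd.DataFrame, dict]:
    """FASTA-ready sequences, one chromosome per gene, with planted G4s.

    Returns ``(sequences, gene_models, ledger)``: sequences keyed by
    chromosome, gene models as a BED12-shaped DataFrame, and the plant
    ledger listing each motif's gene, region, subtype, strand and
    chromosome coordinates.
    """
    config.validate()
    rng = config._rng(3)
    total = sum(c for _, _, c in config.g4_plant_spec)
    n_seq_genes = min(max(total, 4), config.n_genes)
    # chromosome-per-gene, named from the shared gene universe so G4 calls
    # cross-reference the expression/DEG stages
    genes = config.gene_ids()[:n_seq_genes]
    strands = ["+" if i % 2 == 0 else "-" for i in range(n_seq_genes)]

    seqs = {g: _background_sequence(rng, _CHROM_LEN) for g in genes}
    used: dict[str, list[tuple[int, int]]] = {g: [] for g in genes}
    plants = []
    gene_cycle = 0
    for region, subtype, count in config.g4_plant_spec:
        for _ in range(count):
            for attempt in range(200):
                gi = gene_cycle % n_seq_genes
                gene_cycle += 1
                gene = genes[gi]
                strand = strands[gi]
                layout = _PLUS_LAYOUT if strand == "+" else _MINUS_LAYOUT
                lo, hi = layout[region]
                motif = _motif(rng, subtype)
                if len(motif) + 2 > hi - lo:
                    raise ValueError(
                        f"motif of length {len(motif)} does not fit region {region}"
                    )
                start = int(rng.integers(lo + 1, hi - len(motif) - 1))
                end = start + len(motif)
                if any(s < end + 1 and start - 1 < e for s, e in used[gene]):
                    continue
                text = motif if strand == "+" else reverse_complement(motif)
                arr = seqs[gene]
                arr[start:end] = list(text)
                # sanitize flanks so the planted run cannot extend
                arr[start - 1] = "A"
                arr[end] = "T"
                used[gene].append((start, end))
                plants.append(
                    {
                        "gene_id": gene,
                        "chrom": gene,
                        "region": region,
                        "subtype": subtype,
                        "strand": strand,
                        "start": start,
                        "end": end,
                        "sequence": motif,
                    }
                )
                break
            else:
                raise ValueError(f"could not place motif in region {region!r}")

    models = []
    for gene, strand in zip(genes, strands):
        layout = _PLUS_LAYOUT if strand == "+" else _MINUS_LAYOUT
        g_lo, g_hi = layout["gene"]
        c_lo, c_hi = layout["cds"]
        models.append(
            {
                "chrom": gene,
                "start": g_lo,
                "end": g_hi,
                "name": gene,
                "score": 0,
                "strand": strand,
                "thick_start": c_lo,
                "thick_end": c_hi,
                "item_rgb": "0",
                "block_count": 1,
                "block_sizes": f"{g_hi - g_lo},",
                "block_starts": "0,",
            }
        )
    gene_models = pd.DataFrame(models)
    sequences = {g: "".join(seqs[g]) for g in genes}
    ledger = {"plants": plants, "n_planted": len(plants)}
    return sequences, gene_models, ledger


def make_network(
    config: SynthConfig, node_ids: Sequence[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Weighted edge list with planted disjoint cliques on sparse background.

    Clique edges score in (0.5, 1]; background edges, added between any
    node pair not already joined, score in (0, 0.5] with probability
    ``network_background_density``.
    """
    if not config.clique_sizes:
        raise ValueError("clique_sizes must be nonempty")
    rng = config._rng(4)
    n_clique = sum(config.clique_sizes)
    n_nodes = n_clique + config.network_background_nodes
    if node_ids is None:
        node_ids = [f"node{i:03d}" for i in range(1, n_nodes + 1)]
    else:
        node_ids = list(node_ids)
        if len(node_ids) < n_clique:
            raise ValueError(
                f"need at least {n_clique} node ids for the cliques, got {len(node_ids)}"
            )
        # background shrinks to whatever ids remain
        node_ids = node_ids[:n_nodes]

    edges: dict[tuple[str, str], float] = {}
    cliques = []
    pos = 0
    for size in config.clique_sizes:
        members = node_ids[pos : pos + size]
        cliques.append(members)
        for i in range(size):
            for j in range(i + 1, size):
                a, b = sorted((members[i], members[j]))
                edges[(a, b)] = float(rng.uniform(0.5, 1.0))
        pos += size

    clique_of = {v: k for k, members in enumerate(cliques) for v in members}
    if config.network_background_density > 0:
        for i in range(len(node_ids)):
            for j in range(i + 1, len(node_ids)):
                a, b = sorted((node_ids[i], node_ids[j]))
                if (a, b) in edges:
                    continue
                # never densify a planted clique's surroundings into a larger clique:
                # background edges only with the configured sparse probability
                if rng.random() < config.network_background_density:
                    edges[(a, b)] = float(rng.uniform(0.05, 0.5))

    df = pd.DataFrame(
        [(a, b, s) for (a, b), s in sorted(edges.items())],
        columns=["node_a", "node_b", "score"],
    )
    ledger = {"cliques": cliques, "clique_of": clique_of}
    return df, ledger


# ---------------------------------------------------------------------------
# file writers (all plain text; deterministic layout)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed12(gene_models: pd.DataFrame, path: str | Path) -> None:
    gene_models.to_csv(path, sep="\t", header=False, index=False)


def write_all(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every synthetic input and write it under ``outdir``.

    Returns a name -> path map.  Ground-truth ledgers land in
    ``ground_truth.json`` next to the data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, traits, expr_gt = make_expression(config)
    tables, deg_gt = make_deg_tables(config)
    sequences, gene_models, seq_gt = make_sequences(config)
    network, net_gt = make_network(config)

    paths = {}
    paths["expression"] = outdir / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t")
    paths["traits"] = outdir / "traits.tsv"
    traits.to_csv(paths["traits"], sep="\t")
    deg_dir = outdir / "deg"
    deg_dir.mkdir(exist_ok=True)
    for table in tables:
        ds = table.attrs["dataset_id"]
        p = deg_dir / f"{ds}.tsv"
        table.to_csv(p, sep="\t", index=False)
        paths[f"deg:{ds}"] = p
    paths["fasta"] = outdir / "sequences.fa"
    write_fasta(sequences, paths["fasta"])
    paths["bed"] = outdir / "genes.bed"
    write_bed12(gene_models, paths["bed"])
    paths["network"] = outdir / "network.tsv"
    network.to_csv(paths["network"], sep="\t", index=False)

    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(config),
                "expression": expr_gt,
                "deg": deg_gt,
                "sequences": seq_gt,
                "network": net_gt,
            },
            fh,
            indent=1,
            default=str,
        )
    return paths
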