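"""De novo G-quadruplex motif scanning and gene-region annotation.

A putative quadruplex-forming sequence is four runs of guanine separated
by short loops, ``G{m,}(N{1,7}G{m,}){3}``, with a minimum run length of
2 (subtype G2) or 3 (subtype G3).  Both strands are scanned: the minus
strand by applying the same pattern to the reverse complement and
mapping coordinates back.  When both subtypes are requested, a locus
takes its maximal subtype (a G3 hit is not double-counted as G2).

Hits are annotated with every gene-region label they overlap by at
least one base — promoter (a configurable span upstream of the
transcription start, strand-aware), 5'UTR, CDS, exon, 3'UTR, and the
gene span itself — and summarized per gene, region, strand, subtype,
and (optionally) co-expression module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from n4.synthio import reverse_complement

SUBTYPE_MIN_RUN = {"G2": 2, "G3": 3}
REGION_ORDER = ("promoter", "5utr", "exon", "cds", "3utr", "gene")

Span = tuple[int, int]


@dataclass
class GeneModel:
    """One gene's structure in 0-based half-open chromosome coordinates."""

    gene_id: str
    chrom: str
    strand: str
    gene: Span
    exons: list[Span]
    cds: list[Span] = field(default_factory=list)
    utr5: list[Span] = field(default_factory=list)
    utr3: list[Span] = field(default_factory=list)

    def promoter(self, promoter_len: int = 1000) -> Span:
        if self.strand == "+":
            return (max(0, self.gene[0] - promoter_len), self.gene[0])
        return (self.gene[1], self.gene[1] + promoter_len)

    def spans(self, region: str, promoter_len: int = 1000) -> list[Span]:
        return {
            "gene": [self.gene],
            "exon": self.exons,
            "cds": self.cds,
            "5utr": self.utr5,
            "3utr": self.utr3,
            "promoter": [self.promoter(promoter_len)],
        }[region]


def _subtract(spans: list[Span], lo: int, hi: int) -> list[Span]:
    """Parts of ``spans`` inside [lo, hi)."""
    out = []
    for s, e in spans:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Gene models from BED12 (0-based half-open; UTRs from thick bounds)."""
    models = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{line_no}: BED12 needs 12 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            start, end = int(start), int(end)
            thick_s, thick_e = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{line_no}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            cds = _subtract(exons, thick_s, thick_e)
            left = _subtract(exons, start, thick_s)
            right = _subtract(exons, thick_e, end)
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            models.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand, gene=(start, end),
                    exons=exons, cds=cds, utr5=utr5, utr3=utr3,
                )
            )
    return models


_GFF_REGION = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Minimal GFF3 reader: gene + exon/CDS/UTR features, 1-based closed
    coordinates converted to 0-based half-open on read."""
    genes: dict[str, GeneModel] = {}
    feature_parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            span = (int(start) - 1, int(end))
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = tags.get("ID", tags.get("Name", ""))
                genes[gid] = GeneModel(
                    gene_id=gid, chrom=chrom, strand=strand, gene=span, exons=[]
                )
            elif ftype == "mRNA":
                feature_parent[tags.get("ID", "")] = tags.get("Parent", "")
            elif ftype in _GFF_REGION:
                parent = tags.get("Parent", "")
                gid = feature_parent.get(parent, parent)
                if gid in genes:
                    getattr(genes[gid], _GFF_REGION[ftype]).append(span)
    return list(genes.values())


def scan_sequence(
    seq: str,
    subtype: str = "both",
    min_loop: int = 1,
    max_loop: int = 7,
    strands: str = "both",
    overlapping: bool = False,
) -> list[dict]:
    """Leftmost non-overlapping quadruplex matches on one sequence.

    Returns dicts with ``start``, ``end`` (0-based half-open, forward
    coordinates), ``strand``, ``subtype`` and ``matched`` (motif-strand
    sequence).  ``overlapping`` enumerates a match at every start
    position instead (for density studies, not for counting).
    """
    seq = seq.upper()
    bad = re.search(r"[^ACGTN]", seq)
    if bad:
        raise ValueError(
            f"invalid nucleotide {bad.group(0)!r} at position {bad.start()}"
        )
    if not 1 <= min_loop <= max_loop:
        raise ValueError("need max_loop >= min_loop >= 1")
    if subtype not in ("G2", "G3", "both"):
        raise ValueError(f"unknown subtype {subtype!r}")
    subtypes = ["G3", "G2"] if subtype == "both" else [subtype]

    hits: list[dict] = []
    for st in subtypes:
        run = SUBTYPE_MIN_RUN[st]
        pattern = re.compile(
            rf"G{{{run},}}(?:[ACGTN]{{{min_loop},{max_loop}}}G{{{run},}}){{3}}"
        )
        for strand in ("+", "-"):
            if strands != "both" and strand != strands:
                continue
            text = seq if strand == "+" else reverse_complement(seq)
            if overlapping:
                matches = [
                    m
                    for i in range(len(text))
                    if (m := pattern.match(text, i)) is not None
                ]
            else:
                matches = list(pattern.finditer(text))
            for m in matches:
                s, e = m.start(), m.end()
                if strand == "-":
                    s, e = len(seq) - m.end(), len(seq) - m.start()
                hits.append(
                    {"start": s, "end": e, "strand": strand, "subtype": st,
                     "matched": m.group(0)}
                )
    if subtype == "both":
        # a locus takes its maximal subtype: drop G2 hits overlapping a G3 hit
        g3 = [(h["start"], h["end"], h["strand"]) for h in hits if h["subtype"] == "G3"]
        hits = [
            h
            for h in hits
            if h["subtype"] == "G3"
            or not any(
                h["strand"] == st and h["start"] < e and s < h["end"]
                for s, e, st in g3
            )
        ]
    hits.sort(key=lambda h: (h["start"], h["end"], h["strand"]))
    return hits


@dataclass
class G4Hit:
    gene_id: str
    chrom: str
    subtype: str
    strand: str
    start: int
    end: int
    matched: str
    region_labels: set[str] = field(default_factory=set)


def annotate_hits(
    raw_hits: list[dict],
    model: GeneModel,
    promoter_len: int = 1000,
) -> tuple[list[G4Hit], int]:
    """Attach region labels to hits on one gene's chromosome.

    A hit gets every region label whose span it overlaps by >= 1 bp.
    Hits overlapping neither the gene span nor the promoter are dropped;
    the second return value counts them.
    """
    out, dropped = [], 0
    for h in raw_hits:
        labels = set()
        for region in REGION_ORDER:
            spans = model.spans(region, promoter_len)
            if any(h["start"] < e and s < h["end"] for s, e in spans):
                labels.add(region)
        if not labels:
            dropped += 1
            continue
        out.append(
            G4Hit(
                gene_id=model.gene_id, chrom=model.chrom, subtype=h["subtype"],
                strand=h["strand"], start=h["start"], end=h["end"],
                matched=h["matched"], region_labels=labels,
            )
        )
    return out, dropped


def scan_genome(
    sequences: dict[str, str],
    models: list[GeneModel],
    subtype: str = "both",
    min_loop: int = 1,
    max_loop: int = 7,
    promoter_len: int = 1000,
) -> tuple[list[G4Hit], int]:
    """Scan every chromosome and annotate hits against its gene models."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    hits: list[G4Hit] = []
    dropped = 0
    for chrom, seq in sequences.items():
        raw = scan_sequence(seq, subtype=subtype, min_loop=min_loop, max_loop=max_loop)
        if not raw:
            continue
        for model in by_chrom.get(chrom, []):
            annotated, d = annotate_hits(raw, model, promoter_len)
            hits.extend(annotated)
            dropped += d
        if chrom not in by_chrom:
            dropped += len(raw)
    return hits, dropped


@dataclass
class G4Summary:
    genes_with_hits: int
    genes_per_region: dict[str, int]
    hits_per_strand: dict[str, int]
    strand_bias_pct: float | None
    subtype_counts: dict[str, int]
    genes_per_module: dict[str, int] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        rows = [{"metric": "genes_with_hits", "value": self.genes_with_hits}]
        rows += [
            {"metric": f"genes_{r}", "value": c} for r, c in self.genes_per_region.items()
        ]
        rows += [
            {"metric": f"hits_strand_{s}", "value": c}
            for s, c in self.hits_per_strand.items()
        ]
        rows.append({"metric": "strand_bias_pct", "value": self.strand_bias_pct})
        rows += [
            {"metric": f"hits_{t}", "value": c} for t, c in self.subtype_counts.items()
        ]
        rows += [
            {"metric": f"genes_module_{m}", "value": c}
            for m, c in self.genes_per_module.items()
        ]
        return pd.DataFrame(rows)


def summarize(
    hits: list[G4Hit], module_assignment: dict[str, str] | None = None
) -> G4Summary:
    """Per-gene region accounting, strand bias, subtype and module tallies.

    Region counts tally genes, not hits: a gene counts once per region in
    which it has at least one hit.  Strand bias is
    ``(plus - minus) / minus * 100`` (None when no minus-strand hits).
    """
    region_genes: dict[str, set[str]] = {r: set() for r in REGION_ORDER}
    strands = {"+": 0, "-": 0}
    subtypes: dict[str, int] = {}
    genes: set[str] = set()
    for h in hits:
        genes.add(h.gene_id)
        strands[h.strand] += 1
        subtypes[h.subtype] = subtypes.get(h.subtype, 0) + 1
        for r in h.region_labels:
            region_genes[r].add(h.gene_id)
    bias = None
    if strands["-"] > 0:
        bias = (strands["+"] - strands["-"]) / strands["-"] * 100.0
    per_module: dict[str, int] = {}
    if module_assignment:
        for g in genes:
            m = module_assignment.get(g)
            if m is not None:
                per_module[m] = per_module.get(m, 0) + 1
    return G4Summary(
        genes_with_hits=len(genes),
        genes_per_region={r: len(s) for r, s in region_genes.items()},
        hits_per_strand=strands,
        strand_bias_pct=bias,
        subtype_counts=subtypes,
        genes_per_module=per_module,
    )


def write_hits_bed(hits: list[G4Hit], path: str | Path) -> None:
    """Hits as BED6+: name packs gene|subtype|regions."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.chrom, h.start, h.end)):
            regions = ",".join(sorted(h.region_labels))
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.gene_id}|{h.subtype}|{regions}"
                f"\t0\t{h.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
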