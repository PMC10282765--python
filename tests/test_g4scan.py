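"""Quadruplex scanning, region annotation, and summaries."""

import numpy as np
import pytest

from n4 import g4scan, synthio
from n4.g4scan import GeneModel, annotate_hits, scan_sequence, summarize
from oracles import g4_substring_matches


class TestScanSequence:
    def test_canonical_g3_motif_single_full_span_hit(self):
        hits = scan_sequence("GGGAGGGAGGGAGGG", subtype="G3")
        plus = [h for h in hits if h["strand"] == "+"]
        assert len(plus) == 1
        assert (plus[0]["start"], plus[0]["end"]) == (0, 15)
        oracle = g4_substring_matches("GGGAGGGAGGGAGGG", min_run=3)
        assert oracle == [(0, 15)]

    def test_no_g_runs_no_hits(self):
        assert scan_sequence("ATATATAT") == []

    def test_c_motif_is_minus_strand_hit(self):
        hits = scan_sequence("CCCTCCCTCCCTCCC", subtype="G3")
        assert len(hits) == 1
        assert hits[0]["strand"] == "-"
        assert (hits[0]["start"], hits[0]["end"]) == (0, 15)
        assert hits[0]["matched"] == "GGGAGGGAGGGAGGG"

    def test_invalid_character_reported_with_position(self):
        with pytest.raises(ValueError, match="position 4"):
            scan_sequence("ACGTXACGT")

    def test_g2_pattern_nests_g3_and_both_reports_maximal_subtype(self):
        seq = "GGGAGGGAGGGAGGG"
        g2_only = scan_sequence(seq, subtype="G2")
        assert any(h["strand"] == "+" for h in g2_only)  # G2 pattern matches G3 loci
        both = scan_sequence(seq, subtype="both")
        plus = [h for h in both if h["strand"] == "+"]
        assert len(plus) == 1 and plus[0]["subtype"] == "G3"

    def test_g2_motif_not_reported_as_g3(self):
        seq = "GGAGGAGGAGG"
        assert scan_sequence(seq, subtype="G3") == []
        both = [h for h in scan_sequence(seq, subtype="both") if h["strand"] == "+"]
        assert len(both) == 1 and both[0]["subtype"] == "G2"

    def test_overlapping_mode_enumerates_every_start(self):
        seq = "GGGAGGGAGGGAGGGAGGG"  # five G3 runs: two overlapping quadruplexes
        plus = lambda hits: [h for h in hits if h["strand"] == "+"]
        assert len(plus(scan_sequence(seq, "G3"))) == 1
        ov = plus(scan_sequence(seq, "G3", overlapping=True))
        assert [(h["start"], h["end"]) for h in ov] == [(0, 19), (4, 19)]

    def test_loop_bounds_respected(self):
        seq = "GGG" + "A" * 8 + "GGGAGGGAGGG"  # first loop too long
        hits = [h for h in scan_sequence(seq, subtype="G3") if h["strand"] == "+"]
        assert hits == []

    @pytest.mark.parametrize("seed", range(5))
    def test_reverse_complement_swaps_strand_counts(self, seed):
        cfg = synthio.SynthConfig(seed=seed)
        seqs, _, _ = synthio.make_sequences(cfg)
        seq = next(iter(seqs.values()))
        fwd = scan_sequence(seq, subtype="both")
        rev = scan_sequence(synthio.reverse_complement(seq), subtype="both")
        count = lambda hits, s: sum(1 for h in hits if h["strand"] == s)
        assert count(fwd, "+") == count(rev, "-")
        assert count(fwd, "-") == count(rev, "+")


PLUS_MODEL = GeneModel(
    gene_id="g", chrom="chr", strand="+", gene=(1000, 2000),
    exons=[(1000, 2000)], cds=[(1200, 1800)], utr5=[(1000, 1200)],
    utr3=[(1800, 2000)],
)


class TestAnnotate:
    def test_cds_hit_gets_nested_labels(self):
        hits, dropped = annotate_hits(
            [{"start": 1300, "end": 1320, "strand": "+", "subtype": "G3", "matched": "x"}],
            PLUS_MODEL,
        )
        assert dropped == 0
        assert hits[0].region_labels == {"gene", "exon", "cds"}

    def test_upstream_hit_is_promoter_only(self):
        hits, _ = annotate_hits(
            [{"start": 975, "end": 990, "strand": "+", "subtype": "G2", "matched": "x"}],
            PLUS_MODEL,
        )
        assert hits[0].region_labels == {"promoter"}

    def test_minus_strand_promoter_is_downstream_in_forward_coords(self):
        minus = GeneModel(
            gene_id="g", chrom="chr", strand="-", gene=(100, 1100),
            exons=[(100, 1100)], cds=[(300, 900)], utr5=[(900, 1100)],
            utr3=[(100, 300)],
        )
        hits, _ = annotate_hits(
            [{"start": 1150, "end": 1170, "strand": "-", "subtype": "G3", "matched": "x"}],
            minus,
        )
        assert hits[0].region_labels == {"promoter"}

    def test_far_hit_dropped_and_counted(self):
        hits, dropped = annotate_hits(
            [{"start": 5000, "end": 5020, "strand": "+", "subtype": "G2", "matched": "x"}],
            PLUS_MODEL,
            promoter_len=1000,
        )
        assert hits == [] and dropped == 1


class TestPlantedLedgerRecovery:
    def test_perfect_recall_precision_and_region_labels(self, default_config, sequence_fixture):
        seqs, bed, gt = sequence_fixture
        models = {m.gene_id: m for m in _models_from_frame(bed)}
        hits, dropped = g4scan.scan_genome(seqs, list(models.values()), subtype="both")
        assert dropped == 0
        planted = {
            (p["chrom"], p["start"], p["end"], p["strand"], p["subtype"])
            for p in gt["plants"]
        }
        found = {(h.chrom, h.start, h.end, h.strand, h.subtype) for h in hits}
        assert found == planted  # 100% recall and 100% precision
        by_locus = {(h.chrom, h.start, h.end): h for h in hits}
        for p in gt["plants"]:
            h = by_locus[(p["chrom"], p["start"], p["end"])]
            assert p["region"] in h.region_labels


def _models_from_frame(bed_frame):
    import io

    text = bed_frame.to_csv(sep="\t", header=False, index=False)
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".bed", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return g4scan.read_bed12(name)
    finally:
        os.unlink(name)


class TestReaders:
    def test_bed12_reader_reconstructs_synthio_layout(self, sequence_fixture):
        _, bed, _ = sequence_fixture
        models = _models_from_frame(bed)
        plus = [m for m in models if m.strand == "+"][0]
        assert plus.gene == (1000, 2000)
        assert plus.cds == [(1200, 1800)]
        assert plus.utr5 == [(1000, 1200)]
        assert plus.utr3 == [(1800, 2000)]
        minus = [m for m in models if m.strand == "-"][0]
        assert minus.utr5 == [(900, 1100)]
        assert minus.promoter(1000) == (1100, 2100)

    def test_gff3_reader_converts_coordinates(self, tmp_path):
        gff = tmp_path / "t.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneA\n"
            "chr1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=tA;Parent=geneA\n"
            "chr1\tsrc\texon\t1001\t2000\t.\t+\t.\tParent=tA\n"
            "chr1\tsrc\tfive_prime_UTR\t1001\t1200\t.\t+\t.\tParent=tA\n"
            "chr1\tsrc\tCDS\t1201\t1800\t.\t+\t0\tParent=tA\n"
            "chr1\tsrc\tthree_prime_UTR\t1801\t2000\t.\t+\t.\tParent=tA\n"
        )
        models = g4scan.read_gff3(gff)
        assert len(models) == 1
        m = models[0]
        assert m.gene == (1000, 2000)
        assert m.cds == [(1200, 1800)]
        assert m.utr5 == [(1000, 1200)]


class TestSummarize:
    def _hit(self, gene, strand, subtype="G2", regions=("gene",)):
        return g4scan.G4Hit(
            gene_id=gene, chrom=gene, subtype=subtype, strand=strand,
            start=0, end=10, matched="GG", region_labels=set(regions),
        )

    def test_balanced_strands_zero_bias(self):
        hits = [self._hit(f"g{i}", "+") for i in range(10)]
        hits += [self._hit(f"h{i}", "-") for i in range(10)]
        assert summarize(hits).strand_bias_pct == pytest.approx(0.0)

    def test_all_g2_proportion(self):
        hits = [self._hit(f"g{i}", "+", "G2") for i in range(5)]
        s = summarize(hits)
        assert s.subtype_counts == {"G2": 5}

    def test_region_counts_count_genes_not_hits(self):
        hits = [
            self._hit("g1", "+", regions=("gene", "cds")),
            self._hit("g1", "+", regions=("gene", "cds")),  # same gene, 2 hits
            self._hit("g2", "+", regions=("gene",)),
        ]
        s = summarize(hits)
        assert s.genes_per_region["gene"] == 2
        assert s.genes_per_region["cds"] == 1

    def test_module_tallies(self):
        hits = [self._hit("g1", "+"), self._hit("g2", "+"), self._hit("g3", "-")]
        s = summarize(hits, module_assignment={"g1": "turquoise", "g2": "turquoise", "g3": "blue"})
        assert s.genes_per_module == {"turquoise": 2, "blue": 1}

    def test_fixture_region_counts_match_plant_ledger(self, default_config, sequence_fixture):
        seqs, bed, gt = sequence_fixture
        models = _models_from_frame(bed)
        hits, _ = g4scan.scan_genome(seqs, models, subtype="both")
        s = summarize(hits)
        for region in ("promoter", "5utr", "cds", "3utr"):
            planted_genes = {p["gene_id"] for p in gt["plants"] if p["region"] == region}
            assert s.genes_per_region[region] >= len(planted_genes)
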