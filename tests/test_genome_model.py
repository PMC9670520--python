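"""Gene-model loading and region classification against brute-force oracles."""

import numpy as np
import pytest

from bdvp.genome_model import (
    GeneIndex,
    GeneModelError,
    GeneRecord,
    GenomicInterval,
    RegionClass,
    classify_position,
    load_gene_model,
)
from bdvp.synthetic import SimConfig, simulate_gene_model


def _gene(gid, start, end, biotype="protein_coding", exons=(), cds=(), utrs=(), contig="chr1"):
    return GeneRecord(
        gene_id=gid,
        biotype=biotype,
        span=GenomicInterval(contig, start, end),
        exons=[GenomicInterval(contig, a, b) for a, b in exons],
        cds=[GenomicInterval(contig, a, b) for a, b in cds],
        utrs=[GenomicInterval(contig, a, b) for a, b in utrs],
    )


GFF_OK = """##gff-version 3
chr1\tsim\tgene\t101\t600\t.\t+\t.\tID=g1;gene_id=g1;biotype=protein_coding
chr1\tsim\texon\t101\t200\t.\t+\t.\tID=g1.e1;Parent=g1;gene_id=g1
chr1\tsim\texon\t401\t600\t.\t+\t.\tID=g1.e2;Parent=g1;gene_id=g1
chr1\tsim\tCDS\t151\t200\t.\t+\t0\tID=g1.c1;Parent=g1;gene_id=g1
chr1\tsim\tfive_prime_UTR\t101\t150\t.\t+\t.\tID=g1.u1;Parent=g1;gene_id=g1
chr1\tsim\tgene\t1001\t1400\t.\t-\t.\tID=n1;gene_id=n1;biotype=ncRNA
chr1\tsim\texon\t1001\t1200\t.\t-\t.\tID=n1.e1;Parent=n1;gene_id=n1
"""


class TestLoadGeneModel:
    def test_gene_structure_round_trip(self, tmp_path):
        path = tmp_path / "m.gff3"
        path.write_text(GFF_OK)
        genes = load_gene_model(str(path))
        assert [g.gene_id for g in genes] == ["g1", "n1"]
        g1, n1 = genes
        assert len(g1.exons) == 2 and len(g1.cds) == 1 and len(g1.utrs) == 1
        assert g1.span.start == 100 and g1.span.end == 600  # converted to 0-based
        assert n1.biotype == "ncRNA" and n1.cds == []

    def test_cds_outside_exon_rejected(self, tmp_path):
        bad = GFF_OK + "chr1\tsim\tCDS\t701\t800\t.\t+\t0\tID=g1.cx;Parent=g1;gene_id=g1\n"
        path = tmp_path / "bad.gff3"
        path.write_text(bad)
        with pytest.raises(GeneModelError, match="not contained in any exon"):
            load_gene_model(str(path))

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "trunc.gff3"
        path.write_text("##gff-version 3\nchr1\tsim\tgene\t101\n")
        with pytest.raises(GeneModelError, match="line 2"):
            load_gene_model(str(path))


class TestClassifyPosition:
    @pytest.fixture()
    def model(self):
        return [
            _gene("gA", 100, 600, exons=[(100, 200), (400, 600)],
                  cds=[(150, 200), (400, 500)], utrs=[(100, 150), (500, 600)]),
            _gene("gN", 1000, 1400, biotype="ncRNA", exons=[(1000, 1200)]),
        ]

    @pytest.mark.parametrize(
        "pos1, region, genes",
        [
            (180, RegionClass.CODING, ("gA",)),       # inside CDS
            (120, RegionClass.UTR, ("gA",)),          # inside 5' UTR
            (1100, RegionClass.NCRNA, ("gN",)),       # ncRNA exon
            (300, RegionClass.INTRONIC, ("gA",)),     # in span, no exon
            (1250, RegionClass.INTRONIC, ("gN",)),    # ncRNA span, outside exon
            (700, RegionClass.INTERGENIC, ("gA",)),   # nearer gA than gN
        ],
    )
    def test_examples(self, model, pos1, region, genes):
        got_region, got_genes = classify_position("chr1", pos1, model)
        assert (got_region, got_genes) == (region, genes)

    def test_intergenic_tie_returns_both_genes(self):
        # gene spans [100,200) and [300,400); pos0=249/250 probe the midpoint
        model = [_gene("gL", 100, 200, exons=[(100, 200)], cds=[(100, 200)]),
                 _gene("gR", 301, 401, exons=[(301, 401)], cds=[(301, 401)])]
        # brute-force nearest scan to find the exact tie position
        ties = []
        for pos0 in range(200, 301):
            d = {"gL": pos0 - 199, "gR": 301 - pos0}
            dmin = min(d.values())
            if list(d.values()).count(dmin) == 2:
                ties.append(pos0)
        assert ties, "toy geometry must contain a tie"
        for pos0 in ties:
            region, genes = classify_position("chr1", pos0 + 1, model)
            assert region is RegionClass.INTERGENIC
            assert genes == ("gL", "gR")

    def test_coding_wins_over_overlapping_ncrna(self):
        model = [
            _gene("gC", 100, 300, exons=[(100, 300)], cds=[(150, 250)], utrs=[(100, 150), (250, 300)]),
            _gene("gX", 120, 400, biotype="ncRNA", exons=[(120, 400)]),
        ]
        region, genes = classify_position("chr1", 200, model)
        assert region is RegionClass.CODING and genes == ("gC",)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(GeneModelError, match="at least one gene"):
            classify_position("chr1", 5, [])

    def test_contig_without_genes_rejected(self, model):
        with pytest.raises(GeneModelError, match="chr9"):
            classify_position("chr9", 5, model)


def _brute_force(contig, pos1, genes):
    """Independent per-interval scan implementing the precedence rule."""
    pos0 = pos1 - 1
    coding, utr, ncrna, intron = [], [], [], []
    for g in genes:
        if g.span.contig != contig or not (g.span.start <= pos0 < g.span.end):
            continue
        if any(iv.start <= pos0 < iv.end for iv in g.cds):
            coding.append(g.gene_id)
        elif any(iv.start <= pos0 < iv.end for iv in g.utrs):
            utr.append(g.gene_id)
        elif g.biotype == "ncRNA" and any(iv.start <= pos0 < iv.end for iv in g.exons):
            ncrna.append(g.gene_id)
        else:
            intron.append(g.gene_id)
    for region, hits in [
        (RegionClass.CODING, coding),
        (RegionClass.UTR, utr),
        (RegionClass.NCRNA, ncrna),
        (RegionClass.INTRONIC, intron),
    ]:
        if hits:
            return region, tuple(sorted(hits))
    dists = {}
    for g in genes:
        if g.span.contig != contig:
            continue
        if pos0 < g.span.start:
            dists[g.gene_id] = g.span.start - pos0
        else:
            dists[g.gene_id] = pos0 - (g.span.end - 1)
    dmin = min(dists.values())
    return RegionClass.INTERGENIC, tuple(sorted(g for g, d in dists.items() if d == dmin))


class TestOracleEquivalence:
    def test_matches_per_base_scan_on_random_models(self):
        rng = np.random.default_rng(5)
        for trial in range(8):
            cfg = SimConfig(
                n_genes=int(rng.integers(2, 11)),
                contig_length=10_000,
                exon_count_range=(1, 3),
                exon_length_range=(100, 200),
                intron_length_range=(30, 200),
                intergap_range=(20, 300),
                ncrna_fraction=0.3,
                seed=int(rng.integers(10_000)),
            )
            genes = simulate_gene_model(cfg)
            index = GeneIndex(genes)
            positions = rng.integers(1, 10_000, size=300)
            for pos1 in positions:
                assert index.classify("chr1", int(pos1)) == _brute_force("chr1", int(pos1), genes)

    def test_invariant_to_gene_order(self):
        cfg = SimConfig(n_genes=8, contig_length=60_000, seed=3)
        genes = simulate_gene_model(cfg)
        rng = np.random.default_rng(0)
        shuffled = list(genes)
        rng.shuffle(shuffled)
        for pos1 in rng.integers(1, 60_000, size=200):
            assert classify_position("chr1", int(pos1), genes) == classify_position(
                "chr1", int(pos1), shuffled
            )

    def test_every_position_gets_exactly_one_class(self):
        cfg = SimConfig(n_genes=4, contig_length=30_000, seed=9)
        genes = simulate_gene_model(cfg)
        index = GeneIndex(genes)
        for pos1 in range(1, 30_000, 97):
            region, hit = index.classify("chr1", pos1)
            assert isinstance(region, RegionClass) and len(hit) >= 1
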