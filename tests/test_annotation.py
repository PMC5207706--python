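import pytest

from boundary_srna.annotation import (
    ANTISENSE,
    SENSE,
    TERMINUS,
    TSS,
    AnnotationError,
    GeneModel,
    extract_boundary_regions,
    infer_compartment,
    load_gene_models,
    reverse_complement,
    select_longest_model,
)

from conftest import random_sequence


class TestSelectLongestModel:
    def test_longest_of_two_isoforms(self):
        model = select_longest_model(
            "G1", [("Chr1", "+", 1_000, 2_199), ("Chr1", "+", 1_000, 1_899)]
        )
        assert model.body_length == 1_200
        assert (model.tss, model.terminus) == (1_000, 2_199)

    def test_single_isoform_identity(self):
        model = select_longest_model("G1", [("Chr1", "+", 50, 149)])
        assert (model.tss, model.terminus, model.body_length) == (50, 149, 100)

    def test_minus_strand_anchor_assignment(self):
        # genomic span [1000, 2000]: the TSS is the 5'-most transcribed base
        # on the gene strand, i.e. the genomically rightmost one
        model = select_longest_model("G1", [("Chr1", "-", 1_000, 2_000)])
        assert (model.tss, model.terminus) == (2_000, 1_000)

    @pytest.mark.parametrize(
        "records",
        [
            [("Chr1", "+", 1, 10), ("Chr1", "-", 1, 10)],
            [("Chr1", "+", 1, 10), ("Chr2", "+", 1, 10)],
            [],
        ],
    )
    def test_inconsistent_records_rejected(self, records):
        with pytest.raises(AnnotationError):
            select_longest_model("G1", records)


class TestExtractBoundaryRegions:
    def _genome(self, rng, length=20_000):
        return {"Chr1": random_sequence(rng, length)}

    def test_long_gene_tss_region_is_1000_nt(self, rng):
        genome = self._genome(rng)
        model = GeneModel("G1", "Chr1", "+", 10_001, 12_000, 2_000)
        regions = {(r.anchor, r.region_strand): r for r in
                   extract_boundary_regions(model, genome)}
        tss = regions[(TSS, SENSE)]
        # 1-based [9501, 10500] -> 0-based half-open [9500, 10500)
        assert (tss.start, tss.end, tss.L) == (9_500, 10_500, 1_000)
        assert all(r.L == 1_000 for r in regions.values())

    def test_short_gene_rule(self, rng):
        genome = self._genome(rng)
        model = GeneModel("G1", "Chr1", "+", 1_001, 1_300, 300)
        tss = [r for r in extract_boundary_regions(model, genome)
               if r.anchor == TSS and r.region_strand == SENSE][0]
        assert (tss.start, tss.end, tss.L) == (500, 1_300, 800)

    def test_antisense_is_reverse_complement_of_sense(self, rng):
        genome = self._genome(rng)
        model = GeneModel("G1", "Chr1", "-", 5_000, 3_001, 2_000)
        regions = {(r.anchor, r.region_strand): r for r in
                   extract_boundary_regions(model, genome)}
        for anchor in (TSS, TERMINUS):
            sense, anti = regions[(anchor, SENSE)], regions[(anchor, ANTISENSE)]
            assert (sense.start, sense.end) == (anti.start, anti.end)
            assert anti.sequence == reverse_complement(sense.sequence)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_anchor_offset_carries_marker_base(self, rng, strand):
        seq = list(random_sequence(rng, 20_000).replace("N", "A"))
        tss_pos, term_pos = (10_001, 11_000) if strand == "+" else (11_000, 10_001)
        marker = {"+": ("G", "C"), "-": ("C", "G")}[strand]
        seq[tss_pos - 1], seq[term_pos - 1] = marker
        genome = {"Chr1": "".join(seq)}
        model = GeneModel("G1", "Chr1", strand, tss_pos, term_pos, 1_000)
        for r in extract_boundary_regions(model, genome):
            expected = "G" if r.anchor == TSS else "C"
            if r.region_strand == ANTISENSE:
                expected = reverse_complement(expected)
            assert r.sequence[r.anchor_offset] == expected

    def test_genomic_round_trip(self, rng):
        genome = self._genome(rng)
        model = GeneModel("G1", "Chr1", "-", 9_000, 7_001, 2_000)
        for r in extract_boundary_regions(model, genome):
            assert r.to_genomic(0, r.L) == (r.start, r.end)
            chrom = genome[r.chromosome]
            sub = chrom[r.start:r.end]
            assert r.sequence == (sub if r.seq_is_forward else reverse_complement(sub))

    def test_truncation_at_chromosome_start(self, rng):
        genome = self._genome(rng, 3_000)
        model = GeneModel("G1", "Chr1", "+", 101, 1_100, 1_000)
        tss = [r for r in extract_boundary_regions(model, genome)
               if r.anchor == TSS and r.region_strand == SENSE][0]
        assert tss.truncated
        assert (tss.start, tss.end, tss.L) == (0, 600, 600)
        assert tss.anchor_offset == 100

    def test_anchor_outside_genome_rejected(self, rng):
        genome = self._genome(rng, 1_000)
        model = GeneModel("G1", "Chr1", "+", 2_001, 2_100, 100)
        with pytest.raises(AnnotationError):
            extract_boundary_regions(model, genome)


def test_compartment_from_chromosome_name():
    assert infer_compartment("Chr1") == "nuclear"
    assert infer_compartment("ChrC") == "chloroplast"
    assert infer_compartment("ChrM") == "mitochondrial"


def test_load_gene_models_longest_transcript(tmp_path):
    gff = tmp_path / "a.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "Chr1\tx\tgene\t100\t1299\t.\t+\t.\tID=G1\n"
        "Chr1\tx\tmRNA\t100\t999\t.\t+\t.\tID=G1.1;Parent=G1\n"
        "Chr1\tx\tmRNA\t100\t1299\t.\t+\t.\tID=G1.2;Parent=G1\n"
        "Chr1\tx\tgene\t2000\t2500\t.\t-\t.\tID=G2\n"
    )
    models = {m.gene_id: m for m in load_gene_models(gff)}
    assert models["G1"].body_length == 1_200
    # gene without mRNA children falls back to the gene span
    assert (models["G2"].tss, models["G2"].terminus) == (2_500, 2_000)
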