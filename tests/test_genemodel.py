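"""Genome/annotation I/O and coordinate arithmetic."""

import random

import pytest

from splicefate import (
    GeneModelError,
    TranscriptModel,
    intron_sequence,
    read_annotation,
    read_fasta,
    spliced_sequence,
    validate_splice_sites,
    write_gff3,
)

from conftest import build_gene, make_genome, mirror, random_gene


class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n")
        assert read_fasta(p).contigs == {"chr1": "ACGT"}

    def test_lowercase_uppercased_and_description_dropped(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1 some description\nacgt\n>chr2\nttaa\n")
        g = read_fasta(p)
        assert g.contigs == {"chr1": "ACGT", "chr2": "TTAA"}

    def test_illegal_character_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACXT\n")
        with pytest.raises(GeneModelError, match="X"):
            read_fasta(p)

    def test_duplicate_contig_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nACGT\n")
        with pytest.raises(GeneModelError, match="duplicate"):
            read_fasta(p)

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "g.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">chr1\nACGT\n")
        assert read_fasta(p).contigs == {"chr1": "ACGT"}


class TestFetch:
    def test_range_length(self):
        g = make_genome("ACGTACGTAC")
        assert g.fetch("chr1", 2, 5) == "CGTA"
        assert len(g.fetch("chr1", 3, 7)) == 5

    def test_out_of_bounds(self):
        g = make_genome("ACGT")
        with pytest.raises(GeneModelError):
            g.fetch("chr1", 0, 2)
        with pytest.raises(GeneModelError):
            g.fetch("chr1", 3, 5)


GFF3_TOY = """##gff-version 3
chr1\ttest\tmRNA\t11\t100\t.\t+\t.\tID=T1;gene_id=G1
chr1\ttest\texon\t11\t40\t.\t+\t.\tParent=T1
chr1\ttest\texon\t51\t80\t.\t+\t.\tParent=T1
chr1\ttest\texon\t91\t100\t.\t+\t.\tParent=T1
chr1\ttest\tCDS\t16\t40\t.\t+\t0\tParent=T1
chr1\ttest\tCDS\t51\t80\t.\t+\t.\tParent=T1
chr1\ttest\tCDS\t91\t95\t.\t+\t.\tParent=T1
"""

GTF_TOY = """chr1\ttest\ttranscript\t11\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t11\t40\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t51\t80\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t91\t100\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t16\t40\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t51\t80\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t91\t95\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""


class TestReadAnnotation:
    def test_three_exon_gff3(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF3_TOY)
        (model,) = read_annotation(p)
        assert model.transcript_id == "T1"
        assert model.gene_id == "G1"
        assert model.n_exons == 3
        assert model.n_introns == 2
        assert model.exons == ((11, 40), (51, 80), (91, 100))
        # CDS 16-95 genomic -> transcript coords 6..65
        assert (model.cds_start, model.cds_end) == (6, 65)
        assert (model.cds_end - model.cds_start + 1) % 3 == 0

    def test_gtf_dialect_equivalent(self, tmp_path):
        p1 = tmp_path / "a.gff3"
        p1.write_text(GFF3_TOY)
        p2 = tmp_path / "a.gtf"
        p2.write_text(GTF_TOY)
        (m1,) = read_annotation(p1)
        (m2,) = read_annotation(p2)
        assert m1 == m2

    def test_cds_outside_exons_rejected(self, tmp_path):
        bad = GFF3_TOY.replace(
            "chr1\ttest\tCDS\t16\t40", "chr1\ttest\tCDS\t16\t45"
        )
        p = tmp_path / "a.gff3"
        p.write_text(bad)
        with pytest.raises(GeneModelError, match="not contained"):
            read_annotation(p)

    def test_transcript_without_exons_skipped(self, tmp_path, caplog):
        p = tmp_path / "a.gff3"
        p.write_text(
            GFF3_TOY + "chr1\ttest\tmRNA\t200\t300\t.\t+\t.\tID=T2;gene_id=G2\n"
        )
        with caplog.at_level("WARNING"):
            models = read_annotation(p)
        assert [m.transcript_id for m in models] == ["T1"]
        assert "T2" in caplog.text

    def test_roundtrip_gff3(self, tmp_path, rng):
        genome, model = random_gene(rng, n_exons=4)
        out = tmp_path / "rt.gff3"
        write_gff3([model], out)
        (back,) = read_annotation(out)
        assert back == model

    def test_roundtrip_minus_strand(self, tmp_path, rng):
        genome, model = random_gene(rng, n_exons=3, strand="-")
        out = tmp_path / "rt.gff3"
        write_gff3([model], out)
        (back,) = read_annotation(out)
        assert back == model


class TestSplicedSequence:
    def test_lengths_and_junctions(self):
        genome, model = build_gene(
            ["A" * 10, "C" * 20, "T" * 30],
            ["GTAAACAG", "GTTTTCAG"],
        )
        mrna, junctions = spliced_sequence(model, genome)
        assert len(mrna) == 60
        assert junctions.junctions == (10, 30)

    def test_single_exon_empty_junctions(self):
        genome, model = build_gene(["ACGTAC"], [])
        _, junctions = spliced_sequence(model, genome)
        assert junctions.junctions == ()

    def test_strand_symmetry(self, rng):
        for _ in range(25):
            genome, model = random_gene(rng)
            mgenome, mmodel = mirror(genome, model)
            assert spliced_sequence(model, genome) == spliced_sequence(
                mmodel, mgenome
            )

    def test_length_conservation(self, rng):
        for _ in range(25):
            genome, model = random_gene(rng)
            mrna, _ = spliced_sequence(model, genome)
            intron_total = sum(
                model.intron_length(i) for i in range(1, model.n_introns + 1)
            )
            span = model.genomic_span
            assert len(mrna) + intron_total == span[1] - span[0] + 1

    def test_mimic_exon2_is_210nt(self, mimics):
        fx = mimics["slc27a2a_mimic"]
        assert fx.model.exon_lengths[1] == 210
        mrna, _ = spliced_sequence(fx.model, fx.genome)
        assert len(mrna) == fx.model.spliced_length


class TestIntronSequence:
    def test_canonical_boundaries(self, rng):
        genome, model = random_gene(rng, n_exons=4)
        for i in range(1, 4):
            seq = intron_sequence(model, genome, i)
            assert seq.startswith("GT") and seq.endswith("AG")

    def test_minimal_intron(self):
        genome, model = build_gene(["AAA", "CCC"], ["GTAG"])
        assert intron_sequence(model, genome, 1) == "GTAG"

    def test_index_out_of_range(self):
        genome, model = build_gene(["AAA", "CCC"], ["GTAG"])
        with pytest.raises(GeneModelError):
            intron_sequence(model, genome, 2)

    def test_mutated_cd36_intron_starts_atatgt(self, mimics):
        from splicefate import apply_mutation

        fx = mimics["cd36_mimic"]
        mut = apply_mutation(fx.genome, fx.mutation)
        assert intron_sequence(fx.model, mut, 10).startswith("ATATGT")


class TestValidateSpliceSites:
    def test_all_canonical(self, rng):
        genome, model = random_gene(rng)
        assert validate_splice_sites(model, genome) == []

    def test_gc_donor_warned(self):
        genome, model = build_gene(["AAA", "CCC"], ["GCAAAG"])
        warnings = validate_splice_sites(model, genome)
        assert len(warnings) == 1 and "donor" in warnings[0]

    def test_mimics_canonical_premutation(self, mimics):
        for fx in mimics.values():
            assert validate_splice_sites(fx.model, fx.genome) == []

    def test_acceptor_warning_after_mutation(self, mimics):
        from splicefate import apply_mutation

        fx = mimics["abca1b_mimic"]
        mut = apply_mutation(fx.genome, fx.mutation)
        warnings = validate_splice_sites(fx.model, mut)
        assert len(warnings) == 1
        assert "intron 33-34" in warnings[0] and "acceptor" in warnings[0]


class TestModelInvariants:
    def test_short_intron_rejected(self):
        with pytest.raises(GeneModelError, match="intron"):
            TranscriptModel("G", "T", "chr1", "+", ((1, 10), (13, 20)), 1, 9)

    def test_coordinate_mapping_roundtrip(self, rng):
        genome, model = random_gene(rng, strand="-")
        for t in range(1, model.spliced_length + 1):
            g = model.transcript_to_genomic(t)
            assert model.genomic_to_transcript(g) == t
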