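"""HGVS parsing, genome editing, and mutation classification."""

import pytest

from splicefate import (
    Mutation,
    MutationError,
    apply_mutation,
    classify_mutation,
    lift_model,
    parse_hgvs_g,
)

from conftest import build_gene, mirror, random_gene


class TestParseHgvs:
    @pytest.mark.parametrize(
        "text,kind,start,end,ref,alt",
        [
            ("g.3431G>A", "substitution", 3431, 3431, "G", "A"),
            ("g.64427G>T", "substitution", 64427, 64427, "G", "T"),
            ("g.6948_6954del", "deletion", 6948, 6954, "", ""),
            ("g.12del", "deletion", 12, 12, "", ""),
        ],
    )
    def test_supported_forms(self, text, kind, start, end, ref, alt):
        m = parse_hgvs_g(text, contig="chrX")
        assert (m.kind, m.start, m.end, m.ref, m.alt) == (kind, start, end, ref, alt)
        assert m.contig == "chrX"

    def test_inverted_deletion_rejected(self):
        with pytest.raises(MutationError, match="end"):
            parse_hgvs_g("g.10_9del")

    @pytest.mark.parametrize(
        "text", ["g.10dupA", "g.10_11insAC", "g.10_12delinsG", "c.10G>A", "g.10G>"]
    )
    def test_unsupported_forms_rejected(self, text):
        with pytest.raises(MutationError, match="unsupported"):
            parse_hgvs_g(text)


class TestApplyMutation:
    def test_substitution_changes_one_base(self, rng):
        genome, model = random_gene(rng)
        seq = genome.contigs["chr1"]
        mut = Mutation("chr1", "substitution", 5, 5, seq[4], "A" if seq[4] != "A" else "C")
        edited = apply_mutation(genome, mut)
        diff = [i for i, (a, b) in enumerate(zip(seq, edited.contigs["chr1"])) if a != b]
        assert diff == [4]

    def test_deletion_shortens_contig(self, rng):
        genome, _ = random_gene(rng)
        before = len(genome.contigs["chr1"])
        edited = apply_mutation(genome, Mutation("chr1", "deletion", 3, 9, "", ""))
        assert len(edited.contigs["chr1"]) == before - 7

    def test_double_application_guard(self, rng):
        genome, _ = random_gene(rng)
        seq = genome.contigs["chr1"]
        alt = "A" if seq[4] != "A" else "C"
        mut = Mutation("chr1", "substitution", 5, 5, seq[4], alt)
        edited = apply_mutation(genome, mut)
        with pytest.raises(MutationError, match="mismatch"):
            apply_mutation(edited, mut)


class TestLiftModel:
    def test_exonic_deletion_shifts_downstream_exons(self):
        genome, model = build_gene(["ATGAAACCC", "AAATTTCCC", "AAATAA"],
                                   ["GTAACAG", "GTTTCAG"])
        # delete 3 nt inside exon 1
        mut = Mutation("chr1", "deletion", model.exons[0][0] + 3,
                       model.exons[0][0] + 5, "", "")
        lifted = lift_model(model, mut)
        assert lifted.exon_lengths == (6, 9, 6)
        assert lifted.exons[1] == (model.exons[1][0] - 3, model.exons[1][1] - 3)
        assert lifted.cds_end == model.cds_end - 3

    def test_boundary_overlap_rejected(self):
        genome, model = build_gene(["ATGAAACCC", "AAATAA"], ["GTAACAG"])
        mut = Mutation("chr1", "deletion", model.exons[0][1],
                       model.exons[0][1] + 2, "", "")
        with pytest.raises(MutationError, match="boundary"):
            lift_model(model, mut)


def brute_force_category(model, pos):
    """Independent position->ESS category call from first principles."""
    for i in range(1, model.n_introns + 1):
        s, e = model.intron_interval(i)
        if not s <= pos <= e:
            continue
        if model.strand == "+":
            donor = {s, s + 1}
            acceptor = {e - 1, e}
        else:
            donor = {e, e - 1}
            acceptor = {s + 1, s}
        if pos in donor:
            return "ESS_donor", i
        if pos in acceptor:
            return "ESS_acceptor", i
        return "intronic_other", i
    return None


class TestClassify:
    def test_mimic_classifications(self, mimics):
        expected = {
            "slc27a2a_mimic": ("ESS_donor", 2),
            "abca1b_mimic": ("ESS_acceptor", 33),
            "abca1a_mimic": ("ESS_acceptor", 29),
            "cd36_mimic": ("ESS_donor", 10),
            "pla2g12b_mimic": ("ESS_acceptor", 3),
        }
        for name, (cat, intron) in expected.items():
            fx = mimics[name]
            c = classify_mutation(fx.model, fx.genome, fx.mutation)
            assert (c.category, c.affected_intron_index) == (cat, intron)

    def test_nonsense_codon_change(self, mimics):
        fx = mimics["creb3l3a_mimic"]
        c = classify_mutation(fx.model, fx.genome, fx.mutation)
        assert c.category == "exonic_nonsense"
        assert c.codon_change == ("CAA", "TAA")
        assert c.affected_exon_index == 2

    def test_deletion_frameshift_vs_inframe(self, mimics):
        fx = mimics["smyd1a_mimic"]
        c = classify_mutation(fx.model, fx.genome, fx.mutation)
        assert c.category == "exonic_indel_frameshift"
        six = Mutation(fx.mutation.contig, "deletion", fx.mutation.start,
                       fx.mutation.start + 5, "", "")
        c6 = classify_mutation(fx.model, fx.genome, six)
        assert c6.category == "exonic_indel_inframe"

    def test_outside_span_rejected(self, mimics):
        fx = mimics["slc27a2a_mimic"]
        far = Mutation(fx.mutation.contig, "substitution", 10, 10, "A", "C")
        with pytest.raises(MutationError, match="outside"):
            classify_mutation(fx.model, fx.genome, far)

    def test_exactly_four_ess_positions_per_intron(self, rng):
        """Exhaustive intronic scan against a first-principles oracle."""
        for strand in "+-":
            genome, model = random_gene(rng, n_exons=4, strand=strand)
            seq = genome.contigs["chr1"]
            per_intron = {i: {"ESS_donor": 0, "ESS_acceptor": 0}
                          for i in range(1, model.n_introns + 1)}
            span = model.genomic_span
            for pos in range(span[0], span[1] + 1):
                expected = brute_force_category(model, pos)
                if expected is None:
                    continue  # exonic positions handled elsewhere
                ref = seq[pos - 1]
                alt = "A" if ref != "A" else "C"
                got = classify_mutation(
                    model, genome,
                    Mutation("chr1", "substitution", pos, pos, ref, alt),
                )
                assert (got.category, got.affected_intron_index) == expected
                if got.category in per_intron.get(got.affected_intron_index, {}):
                    per_intron[got.affected_intron_index][got.category] += 1
            for counts in per_intron.values():
                assert counts == {"ESS_donor": 2, "ESS_acceptor": 2}

    def test_strand_normalization_invariance(self, rng):
        """Classifying on raw minus-strand coordinates must agree with the
        plus-strand classification of the mirrored gene."""
        for _ in range(10):
            genome, model = random_gene(rng, n_exons=3)
            mgenome, mmodel = mirror(genome, model)
            seq = genome.contigs["chr1"]
            L = len(seq)
            span = model.genomic_span
            for pos in range(span[0], span[1] + 1):
                ref = seq[pos - 1]
                alt = "A" if ref != "A" else "C"
                plus = classify_mutation(
                    model, genome,
                    Mutation("chr1", "substitution", pos, pos, ref, alt),
                )
                from splicefate.genemodel import reverse_complement

                mpos = L - pos + 1
                minus = classify_mutation(
                    mmodel, mgenome,
                    Mutation("chr1", "substitution", mpos, mpos,
                             reverse_complement(ref), reverse_complement(alt)),
                )
                assert plus.category == minus.category
                assert plus.affected_intron_index == minus.affected_intron_index
                assert plus.codon_change == minus.codon_change
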