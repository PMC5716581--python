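"""Cryptic-site scanning and outcome enumeration."""

import random

import pytest

from splicefate import (
    ScanParams,
    apply_mutation,
    classify_mutation,
    enumerate_outcomes,
    lift_model,
    scan_cryptic_sites,
    scan_exon_internal_acceptors,
)
from splicefate.mutation import MutationError, MutationClassification


def naive_scan(sequence, motif, anchor, window, direction="both"):
    """O(n*window) position-by-position dinucleotide check (oracle)."""
    hits = []
    for pos in range(1, len(sequence) - len(motif) + 2):
        offset = pos - anchor
        if abs(offset) > window:
            continue
        if direction == "downstream" and offset < 0:
            continue
        if direction == "upstream" and offset > 0:
            continue
        if all(sequence[pos - 1 + i] == motif[i] for i in range(len(motif))):
            hits.append((offset, pos))
    return sorted(hits, key=lambda h: (abs(h[0]), h[0]))


class TestScanCrypticSites:
    def test_oracle_equivalence_on_random_sequences(self):
        rng = random.Random(42)
        for trial in range(1000):
            n = rng.randint(10, 120)
            seq = "".join(rng.choice("ACGT") for _ in range(n))
            motif = rng.choice(["GT", "AG"])
            anchor = rng.randint(1, n)
            window = rng.randint(1, 60)
            direction = rng.choice(["both", "upstream", "downstream"])
            assert scan_cryptic_sites(seq, motif, anchor, window, direction) == (
                naive_scan(seq, motif, anchor, window, direction)
            ), f"trial {trial}"

    def test_no_motif_empty(self):
        assert scan_cryptic_sites("ACACACAC", "GT", 4, 10) == []

    def test_nearest_first(self):
        #        123456789012
        seq = "AGAAAAAGAAAG"
        hits = scan_cryptic_sites(seq, "AG", 6, 10)
        # nearest first; distance ties resolved to the upstream site
        assert [h[1] for h in hits] == [7, 1, 11]

    def test_n_excluded(self):
        assert scan_cryptic_sites("AANGAG", "AG", 1, 10) == [(4, 5)]


class TestEnumerateDonorLoss:
    def test_slc27a2a_rank1_is_inframe_skip(self, mimics):
        fx = mimics["slc27a2a_mimic"]
        cls = classify_mutation(fx.model, fx.genome, fx.mutation)
        outcomes = enumerate_outcomes(
            fx.model, apply_mutation(fx.genome, fx.mutation), cls
        )
        assert outcomes[0].kind == "exon_skip"
        assert outcomes[0].delta_nt == -210
        assert outcomes[0].rank == 1

    def test_cd36_cryptic_donor_retains_atat(self, mimics):
        fx = mimics["cd36_mimic"]
        cls = classify_mutation(fx.model, fx.genome, fx.mutation)
        outcomes = enumerate_outcomes(
            fx.model, apply_mutation(fx.genome, fx.mutation), cls
        )
        cryptic = [o for o in outcomes if o.kind == "cryptic_donor"]
        assert len(cryptic) == 1
        assert cryptic[0].site_offset == 4
        assert cryptic[0].delta_nt == 4

    def test_ranks_unique_and_ordered(self, mimics):
        for fx in mimics.values():
            if fx.name == "smyd1a_mimic" or fx.name == "creb3l3a_mimic":
                continue
            cls = classify_mutation(fx.model, fx.genome, fx.mutation)
            outcomes = enumerate_outcomes(
                fx.model, apply_mutation(fx.genome, fx.mutation), cls
            )
            assert [o.rank for o in outcomes] == list(range(1, len(outcomes) + 1))
            kinds = [o.kind for o in outcomes]
            if "intron_retention" in kinds:
                assert kinds[-1] == "intron_retention"


class TestEnumerateAcceptorLoss:
    def test_abca1b_rank1_skips_exon34(self, mimics):
        fx = mimics["abca1b_mimic"]
        cls = classify_mutation(fx.model, fx.genome, fx.mutation)
        outcomes = enumerate_outcomes(
            fx.model, apply_mutation(fx.genome, fx.mutation), cls
        )
        assert outcomes[0].kind == "exon_skip"
        assert outcomes[0].delta_nt == -116

    def test_abca1a_cryptic_acceptor_removes_3nt(self, mimics):
        fx = mimics["abca1a_mimic"]
        cls = classify_mutation(fx.model, fx.genome, fx.mutation)
        outcomes = enumerate_outcomes(
            fx.model, apply_mutation(fx.genome, fx.mutation), cls
        )
        cryptic = [o for o in outcomes if o.kind == "cryptic_acceptor"]
        assert len(cryptic) == 1
        assert cryptic[0].site_offset == 3
        assert cryptic[0].delta_nt == -3

    def test_terminal_exon_acceptor_has_no_skip(self, mimics):
        fx = mimics["pla2g12b_mimic"]
        cls = classify_mutation(fx.model, fx.genome, fx.mutation)
        outcomes = enumerate_outcomes(
            fx.model, apply_mutation(fx.genome, fx.mutation), cls
        )
        kinds = {o.kind for o in outcomes}
        assert "exon_skip" not in kinds
        assert "no_rescue" in kinds and "intron_retention" in kinds
        assert outcomes[0].kind == "no_rescue"


class TestDeltaConsistency:
    def test_modified_exons_match_delta(self, mimics):
        """Every outcome's interval chain differs from the wildtype mature
        mRNA length by exactly delta_nt."""
        for fx in mimics.values():
            cls = classify_mutation(fx.model, fx.genome, fx.mutation)
            mut_genome = apply_mutation(fx.genome, fx.mutation)
            lifted = lift_model(fx.model, fx.mutation)
            outcomes = enumerate_outcomes(
                lifted, mut_genome, cls, wildtype_model=fx.model
            )
            if fx.neighbor_exon:
                outcomes += scan_exon_internal_acceptors(
                    lifted, mut_genome, fx.neighbor_exon
                )
            wt_len = fx.model.spliced_length
            for oc in outcomes:
                if oc.kind == "no_rescue":
                    continue
                total = sum(e - s + 1 for s, e in oc.modified_exons)
                expected = wt_len + oc.delta_nt
                if fx.mutation.kind == "deletion" and oc.kind == "cryptic_acceptor":
                    # truncation deltas are measured against the already
                    # deletion-bearing transcript
                    expected = lifted.spliced_length + oc.delta_nt
                assert total == expected, (fx.name, oc.kind, oc.delta_nt)

    def test_unsupported_classification_rejected(self, mimics):
        fx = mimics["slc27a2a_mimic"]
        cls = MutationClassification("exonic_silent", affected_exon_index=2)
        with pytest.raises(MutationError, match="cannot enumerate"):
            enumerate_outcomes(
                fx.model, apply_mutation(fx.genome, fx.mutation), cls
            )


class TestNeighborExonScan:
    def test_smyd1a_truncations_13_and_40(self, mimics):
        fx = mimics["smyd1a_mimic"]
        mut_genome = apply_mutation(fx.genome, fx.mutation)
        lifted = lift_model(fx.model, fx.mutation)
        outcomes = scan_exon_internal_acceptors(lifted, mut_genome, 2)
        assert [o.delta_nt for o in outcomes] == [-13, -40]
        assert [o.site_offset for o in outcomes] == [13, 40]

    def test_exon_without_internal_ag_empty(self, mimics):
        fx = mimics["smyd1a_mimic"]
        assert scan_exon_internal_acceptors(fx.model, fx.genome, 4) == []

    def test_matches_bruteforce_ag_enumeration(self, mimics):
        from splicefate.genemodel import exon_sequence

        fx = mimics["smyd1a_mimic"]
        mut_genome = apply_mutation(fx.genome, fx.mutation)
        lifted = lift_model(fx.model, fx.mutation)
        seq = exon_sequence(lifted, mut_genome, 2)
        expected = [
            p + 1
            for p in range(1, min(100, len(seq) - 2) + 1)
            if seq[p - 1 : p + 1] == "AG"
        ]
        got = [o.site_offset for o in
               scan_exon_internal_acceptors(lifted, mut_genome, 2)]
        assert got == expected


class TestLocality:
    def test_inframe_skip_leaves_downstream_enumeration_unchanged(self, mimics):
        """Enumerating a downstream donor loss yields identical candidates on
        wildtype and mutant genomes when the upstream lesion is exonic."""
        fx = mimics["creb3l3a_mimic"]  # exonic substitution far from intron 5
        cls = MutationClassification("ESS_donor", affected_intron_index=5)
        mut_genome = apply_mutation(fx.genome, fx.mutation)
        wt = enumerate_outcomes(fx.model, fx.genome, cls)
        mut = enumerate_outcomes(fx.model, mut_genome, cls)
        assert wt == mut
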