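"""Prediction pipeline and report rendering.

``predict_one`` runs the full chain for a single (transcript, mutation)
pair: classify the lesion, enumerate ranked splice outcomes, evaluate
each outcome's ORF/PTC/NMD consequence, and (for nonsense mutations with
matrices supplied) annotate exonic-splice-enhancer disruption.  Report
phrases are template-rendered from the structured fields — e.g.
"skipped exon (210 bp), frame maintained" — so identical inputs always
produce identical reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import pandas as pd

from .ese import EseHit, EseMatrix, mutation_in_ese
from .genemodel import GenomeSequence, TranscriptModel, exon_sequence
from .mutation import (
    Mutation,
    MutationClassification,
    apply_mutation,
    classify_mutation,
    lift_model,
)
from .orf import (
    AA_NAMES,
    NmdParams,
    OrfConsequence,
    consequence,
    wildtype_consequence,
)
from .outcomes import (
    PSEUDO_EXON_FLAG,
    ScanParams,
    SpliceOutcome,
    enumerate_outcomes,
    scan_exon_internal_acceptors,
)


@dataclass(frozen=True)
class PredictionRow:
    outcome: SpliceOutcome
    consequence: OrfConsequence
    phrase: str
    transcript_level: str  # 'reduced' | 'WT-like'
    caveats: tuple[str, ...]


@dataclass
class PredictionReport:
    transcript_id: str
    gene_id: str
    mutation: Mutation
    classification: MutationClassification
    wildtype: OrfConsequence
    rows: list[PredictionRow]
    ese_in_enhancer: Optional[bool] = None
    ese_lost_hits: list[EseHit] = field(default_factory=list)

    def row_of_kind(self, kind: str) -> PredictionRow:
        for row in self.rows:
            if row.outcome.kind == kind:
                return row
        raise KeyError(f"no outcome of kind {kind!r} in report")

    @property
    def top(self) -> PredictionRow:
        return self.rows[0]


def render_phrase(
    outcome: SpliceOutcome,
    cons: OrfConsequence,
    classification: MutationClassification,
) -> str:
    maintained = cons.frame_status == "maintained"
    has_ptc = cons.ptc_transcript_pos is not None

    def frame_suffix() -> str:
        if maintained:
            return "frame maintained"
        return "frame shift, PTC" if has_ptc else "frame shift"

    kind = outcome.kind
    if kind == "exon_skip":
        return f"skipped exon ({-outcome.delta_nt} bp), {frame_suffix()}"
    if kind in ("cryptic_donor", "cryptic_acceptor"):
        side = "downstream" if (outcome.site_offset or 0) > 0 else "upstream"
        parts = [f"{side} cryptic splice site used"]
        if maintained and cons.aa_removed == 1 and cons.removed_residues:
            parts.append(
                f"loss of single {AA_NAMES.get(cons.removed_residues, cons.removed_residues)}"
            )
        elif maintained and cons.aa_removed:
            parts.append(f"loss of {cons.aa_removed} AA")
        parts.append(frame_suffix())
        return ", ".join(parts)
    if kind == "intron_retention":
        return f"retained intron ({outcome.delta_nt} bp), {frame_suffix()}"
    if kind == "unspliced_ptc":
        if classification.category.startswith("exonic_indel"):
            return f"(deletion) {frame_suffix()}"
        return "PTC retained in normally spliced transcript"
    if kind == "no_rescue":
        return "terminal-exon acceptor lost; no rescue isoform predicted"
    return kind


def predict_one(
    model: TranscriptModel,
    genome: GenomeSequence,
    mutation: Mutation,
    scan_params: ScanParams = ScanParams(),
    nmd_params: NmdParams = NmdParams(),
    matrices: Optional[list[EseMatrix]] = None,
    neighbor_exon: Optional[int] = None,
) -> PredictionReport:
    """Run the full prediction chain for one (transcript, mutation) pair.

    ``neighbor_exon`` opts in to the internal-acceptor scan of a named
    exon (the phenomenon seen next to an exonic deletion); its truncation
    outcomes are appended after the ranked primary candidates.
    """
    classification = classify_mutation(model, genome, mutation)
    mut_genome = apply_mutation(genome, mutation)
    lifted = lift_model(model, mutation)
    wt = wildtype_consequence(model, genome)

    outcomes = enumerate_outcomes(
        lifted, mut_genome, classification, scan_params, wildtype_model=model
    )
    if neighbor_exon is not None:
        extra = scan_exon_internal_acceptors(
            lifted, mut_genome, neighbor_exon, scan_params
        )
        base = len(outcomes)
        outcomes = outcomes + [
            SpliceOutcome(o.kind, o.modified_exons, o.delta_nt, base + o.rank,
                          o.site_offset, o.description)
            for o in extra
        ]

    rows = []
    for oc in outcomes:
        cons = consequence(oc, lifted, mut_genome, wt, nmd_params)
        caveats = (PSEUDO_EXON_FLAG,) + cons.caveats
        rows.append(
            PredictionRow(
                outcome=oc,
                consequence=cons,
                phrase=render_phrase(oc, cons, classification),
                transcript_level=(
                    "reduced"
                    if cons.transcript_level_class == "reduced"
                    else "WT-like"
                ),
                caveats=caveats,
            )
        )

    report = PredictionReport(
        transcript_id=model.transcript_id,
        gene_id=model.gene_id,
        mutation=mutation,
        classification=classification,
        wildtype=wt,
        rows=rows,
    )

    if matrices and classification.category == "exonic_nonsense":
        k = classification.affected_exon_index
        assert k is not None
        wt_seq = exon_sequence(model, genome, k)
        mut_seq = exon_sequence(model, mut_genome, k)
        t = model.genomic_to_transcript(mutation.start)
        assert t is not None
        offset = t - sum(model.exon_lengths[: k - 1])
        in_ese, lost = mutation_in_ese(wt_seq, mut_seq, offset, matrices)
        report.ese_in_enhancer = in_ese
        report.ese_lost_hits = lost
    return report


# -- serialization -------------------------------------------------------


def report_to_frame(report: PredictionReport) -> pd.DataFrame:
    rows = []
    for r in report.rows:
        rows.append(
            {
                "transcript_id": report.transcript_id,
                "gene_id": report.gene_id,
                "mutation": report.mutation.hgvs_g,
                "category": report.classification.category,
                "rank": r.outcome.rank,
                "kind": r.outcome.kind,
                "delta_nt": r.outcome.delta_nt,
                "site_offset": r.outcome.site_offset,
                "modified_exons": ";".join(
                    f"{s}-{e}" for s, e in r.outcome.modified_exons
                ),
                "frame_status": r.consequence.frame_status,
                "aa_removed": r.consequence.aa_removed,
                "aa_gained": r.consequence.aa_gained,
                "removed_residues": r.consequence.removed_residues,
                "ptc_transcript_pos": r.consequence.ptc_transcript_pos,
                "ptc_distance_to_last_junction": (
                    r.consequence.ptc_distance_to_last_junction
                ),
                "nmd_predicted": r.consequence.nmd_predicted,
                "outcome_on_cdna": r.phrase,
                "predicted_transcript_level": r.transcript_level,
                "in_ese": report.ese_in_enhancer,
                "caveats": "|".join(r.caveats),
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)


def report_to_dict(report: PredictionReport) -> dict:
    return {
        "transcript_id": report.transcript_id,
        "gene_id": report.gene_id,
        "mutation": report.mutation.hgvs_g,
        "classification": asdict(report.classification),
        "ese_in_enhancer": report.ese_in_enhancer,
        "ese_lost_hits": [asdict(h) for h in report.ese_lost_hits],
        "outcomes": [
            {
                "rank": r.outcome.rank,
                "kind": r.outcome.kind,
                "delta_nt": r.outcome.delta_nt,
                "site_offset": r.outcome.site_offset,
                "modified_exons": list(map(list, r.outcome.modified_exons)),
                "description": r.outcome.description,
                "frame_status": r.consequence.frame_status,
                "aa_removed": r.consequence.aa_removed,
                "aa_gained": r.consequence.aa_gained,
                "novel_orf_aa": r.consequence.novel_orf_aa,
                "removed_residues": r.consequence.removed_residues,
                "ptc_transcript_pos": r.consequence.ptc_transcript_pos,
                "ptc_distance_to_last_junction": (
                    r.consequence.ptc_distance_to_last_junction
                ),
                "nmd_predicted": r.consequence.nmd_predicted,
                "outcome_on_cdna": r.phrase,
                "predicted_transcript_level": r.transcript_level,
                "caveats": list(r.caveats),
            }
            for r in report.rows
        ],
    }


def write_report(
    report: PredictionReport, tsv_path, json_path
) -> None:
    report_to_frame(report).to_csv(tsv_path, sep="\t", index=False)
    with open(json_path, "w") as out:
        json.dump(report_to_dict(report), out, indent=2)
        out.write("\n")


# -- mutant-design checklist ---------------------------------------------


def checklist(
    model: TranscriptModel,
    genome: GenomeSequence,
    exon_index: int,
    scan_params: ScanParams = ScanParams(),
    matrices: Optional[list[EseMatrix]] = None,
) -> dict:
    """Pre-design checks for targeting an exon with a mutation.

    Reports (1) cryptic GT/AG candidates near the exon's natural splice
    sites, (2) ESE hits overlapping positions where a single substitution
    would create a stop codon (when matrices are supplied), (3) whether
    the exon length is divisible by 3 (a skip would then preserve frame),
    and (4) flanking intron lengths with a retention-risk flag for short
    introns.
    """
    from .genemodel import intron_sequence
    from .outcomes import scan_cryptic_sites

    if not 1 <= exon_index <= model.n_exons:
        raise ValueError(f"exon index {exon_index} out of range")
    length = model.exon_lengths[exon_index - 1]
    result: dict = {
        "transcript_id": model.transcript_id,
        "exon_index": exon_index,
        "exon_length": length,
        "divisible_by_3": length % 3 == 0,
        "skip_tolerance": (
            "divisible by 3: skip-tolerant"
            if length % 3 == 0
            else f"not divisible by 3 (remainder {length % 3})"
        ),
    }

    exon_seq = exon_sequence(model, genome, exon_index)
    # acceptor side: intron upstream + exon, anchor at the natural AG
    if exon_index > 1:
        iseq = intron_sequence(model, genome, exon_index - 1)
        region = iseq + exon_seq
        anchor = len(iseq) - 1
        hits = [
            {"offset": off, "position": pos}
            for off, pos in scan_cryptic_sites(
                region, scan_params.acceptor_motif, anchor, scan_params.window_nt
            )
            if off != 0
        ]
        up_len = len(iseq)
        result["upstream_intron_length"] = up_len
        result["upstream_intron_retention_risk"] = (
            up_len <= scan_params.intron_retention_max_nt
        )
        result["cryptic_acceptors_near_site"] = hits
    # donor side: exon + intron downstream, anchor at the natural GT
    if exon_index < model.n_exons:
        iseq = intron_sequence(model, genome, exon_index)
        region = exon_seq + iseq
        anchor = len(exon_seq) + 1
        hits = [
            {"offset": off, "position": pos}
            for off, pos in scan_cryptic_sites(
                region, scan_params.donor_motif, anchor, scan_params.window_nt
            )
            if off != 0
        ]
        result["downstream_intron_length"] = len(iseq)
        result["downstream_intron_retention_risk"] = (
            len(iseq) <= scan_params.intron_retention_max_nt
        )
        result["cryptic_donors_near_site"] = hits

    if matrices:
        from .ese import scan_ese
        from .mutation import STOP_CODONS

        offset0 = sum(model.exon_lengths[: exon_index - 1])
        nonsense_positions = []
        for j in range(1, length + 1):
            t = offset0 + j
            if not model.cds_start <= t <= model.cds_end - 3:
                continue
            cds_off = t - model.cds_start
            codon_start_t = model.cds_start + (cds_off // 3) * 3
            # codon in transcript orientation; may span exon boundaries
            mrna_needed = range(codon_start_t, codon_start_t + 3)
            codon = "".join(
                exon_seq[p - offset0 - 1]
                if offset0 < p <= offset0 + length
                else _mrna_base(model, genome, p)
                for p in mrna_needed
            )
            within = cds_off % 3
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                if codon[:within] + alt + codon[within + 1 :] in STOP_CODONS:
                    nonsense_positions.append(j)
                    break
        hits = scan_ese(exon_seq, matrices)
        by_name = {m.name: len(m) for m in matrices}
        overlapping = [
            h
            for h in hits
            if any(
                h.covers(j, by_name[h.matrix_name]) for j in nonsense_positions
            )
        ]
        result["n_candidate_nonsense_positions"] = len(nonsense_positions)
        result["ese_hits_in_exon"] = len(hits)
        result["ese_hits_over_nonsense_positions"] = [
            {"matrix": h.matrix_name, "start": h.start, "score": h.score}
            for h in overlapping
        ]
    return result


def _mrna_base(model: TranscriptModel, genome: GenomeSequence, tpos: int) -> str:
    g = model.transcript_to_genomic(tpos)
    base = genome.fetch(model.contig, g, g)
    if model.strand == "-":
        from .genemodel import reverse_complement

        base = reverse_complement(base)
    return base
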