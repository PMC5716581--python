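"""Open-reading-frame and nonsense-mediated-decay consequences.

Each candidate splice outcome is turned into a mature mRNA, translated
from the wildtype start codon, and examined for a premature termination
codon (PTC).  NMD susceptibility follows the exon-junction-complex rule:
a transcript escapes decay when its PTC lies in the last exon or within
50-55 nt upstream of the last exon-exon junction; the default threshold
here is 55 nt (the permissive end of the published range) so that a
junction-adjacent PTC is robustly called an escape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .genemodel import (
    GenomeSequence,
    JunctionMap,
    TranscriptModel,
    reverse_complement,
    spliced_sequence,
)
from .outcomes import SpliceOutcome

logger = logging.getLogger(__name__)

AA_NAMES = {
    "A": "Alanine", "R": "Arginine", "N": "Asparagine", "D": "Aspartate",
    "C": "Cysteine", "E": "Glutamate", "Q": "Glutamine", "G": "Glycine",
    "H": "Histidine", "I": "Isoleucine", "L": "Leucine", "K": "Lysine",
    "M": "Methionine", "F": "Phenylalanine", "P": "Proline", "S": "Serine",
    "T": "Threonine", "W": "Tryptophan", "Y": "Tyrosine", "V": "Valine",
}


@dataclass(frozen=True)
class NmdParams:
    """escape_threshold_nt: maximum PTC-to-last-junction distance (nt,
    upstream) still escaping decay; published range 50-55."""

    escape_threshold_nt: int = 55

    def __post_init__(self) -> None:
        if not 50 <= self.escape_threshold_nt <= 55:
            logger.warning(
                "NMD escape threshold %d nt outside the published 50-55 nt "
                "range", self.escape_threshold_nt,
            )


@dataclass(frozen=True)
class OrfConsequence:
    mature_mrna: str
    protein: str
    frame_status: str  # maintained | frameshift
    novel_orf_aa: int
    ptc_transcript_pos: Optional[int]
    ptc_distance_to_last_junction: Optional[int]
    nmd_predicted: str  # degraded | escape | not_applicable
    aa_removed: int
    aa_gained: int
    removed_residues: str
    transcript_level_class: str  # reduced | WT_like
    caveats: tuple[str, ...] = ()


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate ``cds`` up to (not including) the first stop codon.

    Returns (protein, stop_found).  Trailing partial codons are ignored.
    """
    usable = cds[: len(cds) - len(cds) % 3]
    full = str(Seq(usable).translate())
    stop = full.find("*")
    if stop == -1:
        return full, False
    return full[:stop], True


def classify_nmd(
    ptc_pos: int, junctions: JunctionMap, params: NmdParams = NmdParams()
) -> str:
    """'escape' when the PTC is downstream of the last exon-exon junction or
    within the escape threshold upstream of it, else 'degraded'.
    Single-exon transcripts always escape."""
    last = junctions.last
    if last is None:
        return "escape"
    distance = last - ptc_pos
    return "escape" if distance <= params.escape_threshold_nt else "degraded"


def diff_protein(
    wt_protein: str, mut_protein: str
) -> tuple[int, int, str, str]:
    """Longest-common-prefix/suffix decomposition of two proteins.

    Returns (aa_removed, aa_gained, removed_residues, frame_status);
    removed_residues is reported only when at most 3 residues are lost.
    The frame is called maintained when everything after the shared prefix
    of the shorter protein is covered by the shared suffix, i.e. the
    mutant's downstream sequence realigns with the wildtype's.
    """
    lcp = 0
    while (
        lcp < len(wt_protein)
        and lcp < len(mut_protein)
        and wt_protein[lcp] == mut_protein[lcp]
    ):
        lcp += 1
    lcs = 0
    while (
        lcs < len(wt_protein) - lcp
        and lcs < len(mut_protein) - lcp
        and wt_protein[len(wt_protein) - 1 - lcs]
        == mut_protein[len(mut_protein) - 1 - lcs]
    ):
        lcs += 1
    aa_removed = len(wt_protein) - lcp - lcs
    aa_gained = len(mut_protein) - lcp - lcs
    removed = (
        wt_protein[lcp : len(wt_protein) - lcs] if 0 < aa_removed <= 3 else ""
    )
    tail = min(len(wt_protein), len(mut_protein)) - lcp
    frame = "maintained" if tail <= lcs else "frameshift"
    return aa_removed, aa_gained, removed, frame


def splice_intervals(
    intervals: tuple[tuple[int, int], ...],
    contig: str,
    strand: str,
    genome: GenomeSequence,
) -> tuple[str, JunctionMap]:
    """Mature mRNA and junction map for an arbitrary exon-interval chain."""
    parts = []
    for s, e in intervals:
        seq = genome.fetch(contig, s, e)
        parts.append(seq if strand == "+" else reverse_complement(seq))
    junctions = []
    total = 0
    for p in parts[:-1]:
        total += len(p)
        junctions.append(total)
    return "".join(parts), JunctionMap(tuple(junctions))


def _position_in_intervals(
    intervals, strand: str, gpos: int
) -> Optional[int]:
    offset = 0
    for s, e in intervals:
        if s <= gpos <= e:
            return offset + (gpos - s + 1 if strand == "+" else e - gpos + 1)
        offset += e - s + 1
    return None


def wildtype_consequence(
    model: TranscriptModel, genome: GenomeSequence
) -> OrfConsequence:
    """Reference ORF record for the unmutated transcript."""
    mrna, _ = spliced_sequence(model, genome)
    protein, stop = translate_cds(mrna[model.cds_start - 1 : model.cds_end])
    if not stop:
        logger.warning("%s: wildtype CDS has no stop codon", model.transcript_id)
    return OrfConsequence(
        mature_mrna=mrna,
        protein=protein,
        frame_status="maintained",
        novel_orf_aa=0,
        ptc_transcript_pos=None,
        ptc_distance_to_last_junction=None,
        nmd_predicted="not_applicable",
        aa_removed=0,
        aa_gained=0,
        removed_residues="",
        transcript_level_class="WT_like",
    )


def consequence(
    outcome: SpliceOutcome,
    model: TranscriptModel,
    mutated_genome: GenomeSequence,
    wildtype: OrfConsequence,
    params: NmdParams = NmdParams(),
) -> OrfConsequence:
    """Evaluate one splice outcome into an ORF/NMD consequence record.

    ``model`` must be in the mutated genome's coordinates (identical to the
    wildtype model for substitutions, deletion-lifted otherwise).  The CDS
    is re-mapped from the wildtype start codon's genomic anchor; the first
    in-frame stop strictly upstream of where the wildtype stop maps is a
    PTC.  A no_rescue outcome (terminal-exon acceptor loss with no
    candidate isoform) is reported as reduced with a caveat, since decay
    is presumed rather than derived from a PTC.
    """
    if outcome.kind == "no_rescue":
        return OrfConsequence(
            mature_mrna="",
            protein="",
            frame_status="maintained",
            novel_orf_aa=0,
            ptc_transcript_pos=None,
            ptc_distance_to_last_junction=None,
            nmd_predicted="not_applicable",
            aa_removed=0,
            aa_gained=0,
            removed_residues="",
            transcript_level_class="reduced",
            caveats=(
                "no rescue isoform identified; transcript loss presumed, "
                "not derived from a PTC",
            ),
        )

    mrna, junctions = splice_intervals(
        outcome.modified_exons, model.contig, model.strand, mutated_genome
    )
    g_start = model.transcript_to_genomic(model.cds_start)
    t_start = _position_in_intervals(outcome.modified_exons, model.strand, g_start)
    if t_start is None:
        return OrfConsequence(
            mature_mrna=mrna,
            protein="",
            frame_status="maintained",
            novel_orf_aa=0,
            ptc_transcript_pos=None,
            ptc_distance_to_last_junction=None,
            nmd_predicted="not_applicable",
            aa_removed=len(wildtype.protein),
            aa_gained=0,
            removed_residues="",
            transcript_level_class="WT_like",
            caveats=("start-lost: outcome removes the initiation codon",),
        )

    protein, stop_found = translate_cds(mrna[t_start - 1 :])
    stop_pos = t_start + 3 * len(protein) if stop_found else None

    # where does the wildtype stop codon land in this transcript?
    g_wt_stop = model.transcript_to_genomic(model.cds_end - 2)
    mapped_wt_stop = _position_in_intervals(
        outcome.modified_exons, model.strand, g_wt_stop
    )
    is_ptc = stop_found and (
        mapped_wt_stop is None or stop_pos < mapped_wt_stop
    )

    aa_removed, aa_gained, removed, frame = diff_protein(
        wildtype.protein, protein
    )
    novel = aa_gained if frame == "frameshift" else 0

    if is_ptc:
        nmd = classify_nmd(stop_pos, junctions, params)
        distance = junctions.last - stop_pos if junctions.last else None
    else:
        nmd = "not_applicable"
        distance = None
    caveats = ()
    if not stop_found:
        caveats = ("open reading frame runs off the transcript end",)
    return OrfConsequence(
        mature_mrna=mrna,
        protein=protein,
        frame_status=frame,
        novel_orf_aa=novel,
        ptc_transcript_pos=stop_pos if is_ptc else None,
        ptc_distance_to_last_junction=distance,
        nmd_predicted=nmd,
        aa_removed=aa_removed,
        aa_gained=aa_gained,
        removed_residues=removed,
        transcript_level_class="reduced" if nmd == "degraded" else "WT_like",
        caveats=caveats,
    )


def residues_encoded_by_exon(
    model: TranscriptModel, exon_index: int
) -> tuple[int, int]:
    """1-based protein residue index range whose codons overlap the coding
    part of ``exon_index``; (0, -1) when the exon is non-coding.  The stop
    codon is not a residue and is excluded."""
    offset = sum(model.exon_lengths[: exon_index - 1])
    length = model.exon_lengths[exon_index - 1]
    lo = max(model.cds_start, offset + 1)
    hi = min(model.cds_end - 3, offset + length)  # exclude stop codon
    if lo > hi:
        return (0, -1)
    first = (lo - model.cds_start) // 3 + 1
    last = (hi - model.cds_start) // 3 + 1
    return first, last
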