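"""Parsing, applying and classifying genomic mutations.

Supports the HGVS genomic subset the study design needs: single-base
substitutions (``g.3431G>A``) and small deletions (``g.6948_6954del``).
Classification reproduces the mutation categories of the mutant lines:
essential-splice-site (ESS) donor/acceptor hits at intron positions
+1/+2 and -2/-1, exonic nonsense/missense/silent substitutions judged in
the transcript reading frame, and in-frame vs frameshifting exonic
deletions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Optional

from Bio.Seq import Seq

from .genemodel import (
    GeneModelError,
    GenomeSequence,
    TranscriptModel,
    spliced_sequence,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class MutationError(ValueError):
    pass


@dataclass(frozen=True)
class Mutation:
    """A genomic edit in plus-strand coordinates (1-based inclusive)."""

    contig: str
    kind: str  # substitution | deletion | insertion
    start: int
    end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise MutationError(f"unknown mutation kind {self.kind!r}")
        if self.end < self.start:
            raise MutationError(f"end {self.end} < start {self.start}")
        if self.kind == "substitution" and not (
            len(self.ref) == len(self.alt) == 1
        ):
            raise MutationError("substitutions must be single-base")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def hgvs_g(self) -> str:
        if self.kind == "substitution":
            return f"g.{self.start}{self.ref}>{self.alt}"
        if self.kind == "deletion":
            return f"g.{self.start}_{self.end}del"
        return f"g.{self.start}_{self.end}ins{self.alt}"


_SUB_RE = re.compile(r"^g\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^g\.(\d+)_(\d+)del$")
_DEL1_RE = re.compile(r"^g\.(\d+)del$")
_UNSUPPORTED_RE = re.compile(r"(dup|ins|delins|inv|>)")


def parse_hgvs_g(text: str, contig: str = "") -> Mutation:
    """Parse the supported HGVS g. subset into a Mutation.

    The contig is not part of g. notation and is supplied separately
    (CLI flag or batch-file column).
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        return Mutation(contig, "substitution", pos, pos, m.group(2), m.group(3))
    m = _DEL_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:
            raise MutationError(f"{text}: deletion end {end} < start {start}")
        return Mutation(contig, "deletion", start, end, "", "")
    m = _DEL1_RE.match(text)
    if m:
        pos = int(m.group(1))
        return Mutation(contig, "deletion", pos, pos, "", "")
    raise MutationError(
        f"unsupported notation {text!r}: only g.<pos><REF>><ALT> and "
        "g.<start>_<end>del are supported"
    )


def apply_mutation(genome: GenomeSequence, mutation: Mutation) -> GenomeSequence:
    """Return an edited genome; the ref field must match the wildtype sequence.

    For deletions with an empty ref field the deleted sequence is recorded
    implicitly by coordinates.  Applying a substitution twice raises a
    ref-mismatch error, which guards against double application.
    """
    seq = genome.contigs.get(mutation.contig)
    if seq is None:
        raise MutationError(f"unknown contig {mutation.contig!r}")
    if mutation.end > len(seq):
        raise MutationError(
            f"mutation {mutation.hgvs_g} beyond contig end ({len(seq)})"
        )
    found = seq[mutation.start - 1 : mutation.end]
    if mutation.ref and found != mutation.ref:
        raise MutationError(
            f"{mutation.hgvs_g}: reference mismatch, expected "
            f"{mutation.ref!r} but genome has {found!r}"
        )
    if mutation.kind == "substitution":
        edited = seq[: mutation.start - 1] + mutation.alt + seq[mutation.start :]
    elif mutation.kind == "deletion":
        edited = seq[: mutation.start - 1] + seq[mutation.end :]
    else:
        edited = seq[: mutation.start - 1] + mutation.alt + seq[mutation.start - 1 :]
    return genome.with_contig(mutation.contig, edited)


def lift_model(model: TranscriptModel, mutation: Mutation) -> TranscriptModel:
    """Shift transcript coordinates onto the mutated genome.

    Substitutions leave coordinates unchanged.  For a deletion, exon
    boundaries strictly downstream (in genomic coordinates) shift left by
    the deleted length; a deletion overlapping an exon boundary is rejected
    as unsupported.  CDS transcript coordinates shrink when the deletion
    removes coding sequence.
    """
    if mutation.kind == "substitution":
        return model
    if mutation.kind != "deletion":
        raise MutationError(f"cannot lift over {mutation.kind}")
    d = mutation.length
    new_exons = []
    for s, e in model.exons:
        crosses_start = mutation.start <= s <= mutation.end
        crosses_end = mutation.start <= e <= mutation.end
        inside = s <= mutation.start and mutation.end <= e
        if (crosses_start or crosses_end) and not inside:
            raise MutationError(
                f"deletion {mutation.hgvs_g} overlaps an exon boundary; "
                "unsupported"
            )
        if inside:
            new_exons.append((s, e - d))
        elif s > mutation.end:
            new_exons.append((s - d, e - d))
        else:
            new_exons.append((s, e))
    cds_start, cds_end = model.cds_start, model.cds_end
    t = model.genomic_to_transcript(mutation.start)
    if t is not None:  # exonic deletion: transcript shrinks at t
        if t < cds_start:
            cds_start -= d
            cds_end -= d
        elif t <= cds_end:
            cds_end -= d
    return replace(
        model, exons=tuple(new_exons), cds_start=cds_start, cds_end=cds_end
    )


@dataclass(frozen=True)
class MutationClassification:
    category: str
    affected_intron_index: Optional[int] = None
    affected_exon_index: Optional[int] = None
    codon_change: Optional[tuple[str, str]] = None


def _codon_category(wt: str, mut: str) -> str:
    if wt in STOP_CODONS:
        return "exonic_silent" if mut in STOP_CODONS else "exonic_missense"
    if mut in STOP_CODONS:
        return "exonic_nonsense"
    if str(Seq(wt).translate()) == str(Seq(mut).translate()):
        return "exonic_silent"
    return "exonic_missense"


def classify_mutation(
    model: TranscriptModel, genome: GenomeSequence, mutation: Mutation
) -> MutationClassification:
    """Categorize a mutation relative to a transcript model.

    Intron positions +1/+2 (transcript orientation) are the ESS donor,
    -2/-1 the ESS acceptor.  Exonic substitutions inside the CDS are
    compared codon-wise in the wildtype reading frame; exonic deletions
    are frameshifting iff their length is not divisible by 3.
    """
    span = model.genomic_span
    if mutation.end < span[0] or mutation.start > span[1]:
        raise MutationError(
            f"mutation {mutation.hgvs_g} outside transcript span "
            f"{span[0]}-{span[1]}"
        )
    if mutation.kind == "substitution":
        pos = mutation.start
        intron = model.intron_index_of(pos)
        if intron is not None:
            d = model.intron_offset_from_donor(intron, pos)
            length = model.intron_length(intron)
            if d in (1, 2):
                return MutationClassification("ESS_donor", affected_intron_index=intron)
            if d in (length - 1, length):
                return MutationClassification(
                    "ESS_acceptor", affected_intron_index=intron
                )
            return MutationClassification(
                "intronic_other", affected_intron_index=intron
            )
        exon = model.exon_index_of(pos)
        if exon is None:
            return MutationClassification("intronic_other")
        t = model.genomic_to_transcript(pos)
        assert t is not None
        if not model.cds_start <= t <= model.cds_end:
            return MutationClassification("utr", affected_exon_index=exon)
        mrna, _ = spliced_sequence(model, genome)
        cds_off = t - model.cds_start  # 0-based within CDS
        codon_i = cds_off // 3
        codon_start = model.cds_start - 1 + codon_i * 3  # 0-based in mRNA
        wt_codon = mrna[codon_start : codon_start + 3]
        alt_t = mutation.alt if model.strand == "+" else str(
            Seq(mutation.alt).complement()
        )
        within = cds_off % 3
        mut_codon = (
            wt_codon[:within] + alt_t + wt_codon[within + 1 :]
        )
        return MutationClassification(
            _codon_category(wt_codon, mut_codon),
            affected_exon_index=exon,
            codon_change=(wt_codon, mut_codon),
        )
    if mutation.kind == "deletion":
        exon = model.exon_index_of(mutation.start)
        exon_end = model.exon_index_of(mutation.end)
        if exon is not None and exon == exon_end:
            cat = (
                "exonic_indel_inframe"
                if mutation.length % 3 == 0
                else "exonic_indel_frameshift"
            )
            return MutationClassification(cat, affected_exon_index=exon)
        if exon is None and exon_end is None:
            intron = model.intron_index_of(mutation.start)
            if intron is not None and intron == model.intron_index_of(mutation.end):
                d1 = model.intron_offset_from_donor(intron, mutation.start)
                d2 = model.intron_offset_from_donor(intron, mutation.end)
                length = model.intron_length(intron)
                lo, hi = min(d1, d2), max(d1, d2)
                if lo <= 2:
                    return MutationClassification(
                        "ESS_donor", affected_intron_index=intron
                    )
                if hi >= length - 1:
                    return MutationClassification(
                        "ESS_acceptor", affected_intron_index=intron
                    )
                return MutationClassification(
                    "intronic_other", affected_intron_index=intron
                )
        raise MutationError(
            f"deletion {mutation.hgvs_g} spans a feature boundary; unsupported"
        )
    raise MutationError(f"cannot classify {mutation.kind}")
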