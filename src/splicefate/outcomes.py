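"""Enumeration of candidate alternative mRNA-processing outcomes.

When an essential splice site is destroyed, the spliceosome's observed
rescue repertoire is, in order of frequency: skipping the affected exon,
activating a nearby cryptic splice site, and retaining the intron (for
short or terminal introns).  This module enumerates those candidates for
a classified mutation, ranked in that order, scanning for cryptic
GT/AG dinucleotides within a configurable window of the lost site.
Pseudo-exon creation via cryptic start sites is deliberately not
enumerated; prediction reports carry a fixed "pseudo-exon not evaluated"
flag instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .genemodel import (
    GeneModelError,
    GenomeSequence,
    TranscriptModel,
    exon_sequence,
    intron_sequence,
)
from .mutation import MutationClassification, MutationError

logger = logging.getLogger(__name__)

PSEUDO_EXON_FLAG = "pseudo-exon not evaluated"

_KIND_PRIORITY = {
    "exon_skip": 0,
    "no_rescue": 0,
    "unspliced_ptc": 0,
    "cryptic_donor": 1,
    "cryptic_acceptor": 1,
    "intron_retention": 2,
}


@dataclass(frozen=True)
class ScanParams:
    """Knobs for cryptic-site scanning and intron-retention proposals.

    window_nt: scan distance on each side of the lost site (nt).  The
        cryptic sites observed in the mutant lines lie 2-40 nt away, so the
        default of 100 is generous while keeping reports short.
    intron_retention_max_nt: retention is proposed for introns at most this
        long; terminal introns are always proposed.
    """

    window_nt: int = 100
    intron_retention_max_nt: int = 1000
    donor_motif: str = "GT"
    acceptor_motif: str = "AG"

    def __post_init__(self) -> None:
        if self.window_nt < 1:
            raise ValueError("window_nt must be >= 1")
        if len(self.donor_motif) != 2 or len(self.acceptor_motif) != 2:
            raise ValueError("splice-site motifs must be dinucleotides")


@dataclass(frozen=True)
class SpliceOutcome:
    """One candidate alternative processing event.

    modified_exons: genomic intervals of the predicted mature transcript, in
        transcription order (on the mutated genome's coordinates).
    delta_nt: signed change in mature-mRNA length vs wildtype.
    site_offset: for cryptic kinds, offset of the cryptic dinucleotide's
        first base from the first base of the wildtype site (signed,
        transcript orientation; positive = downstream).
    """

    kind: str
    modified_exons: tuple[tuple[int, int], ...]
    delta_nt: int
    rank: int = 0
    site_offset: Optional[int] = None
    description: str = ""


def scan_cryptic_sites(
    sequence: str,
    motif: str,
    anchor: int,
    window: int,
    direction: str = "both",
) -> list[tuple[int, int]]:
    """Find every occurrence of ``motif`` whose first base is within
    ``window`` nt of ``anchor`` (a 1-based position in ``sequence``).

    Returns (offset, position) pairs sorted nearest-first, offset being
    position - anchor.  Matches overlapping an N are never reported.
    """
    if not 1 <= anchor <= len(sequence):
        raise GeneModelError(f"anchor {anchor} outside sequence")
    if direction not in ("downstream", "upstream", "both"):
        raise ValueError(f"bad direction {direction!r}")
    if "N" in sequence[max(0, anchor - window - 1) : anchor + window]:
        logger.warning("N base(s) inside scan window; matches there suppressed")
    hits = []
    lo = max(1, anchor - window)
    hi = min(len(sequence) - len(motif) + 1, anchor + window)
    for pos in range(lo, hi + 1):
        offset = pos - anchor
        if direction == "downstream" and offset < 0:
            continue
        if direction == "upstream" and offset > 0:
            continue
        if sequence[pos - 1 : pos - 1 + len(motif)] == motif:
            hits.append((offset, pos))
    hits.sort(key=lambda h: (abs(h[0]), h[0]))
    return hits


def _strip_exon(model, index):
    """Exon intervals with exon ``index`` removed."""
    return tuple(iv for i, iv in enumerate(model.exons, start=1) if i != index)


def _merge_intron(model, intron_index):
    """Exon intervals with intron ``intron_index`` retained (exons merged)."""
    exons = list(model.exons)
    a = exons[intron_index - 1]
    b = exons[intron_index]
    merged = (min(a[0], b[0]), max(a[1], b[1]))
    return tuple(exons[: intron_index - 1] + [merged] + exons[intron_index + 1 :])


def _resize_exon(model, index, trim_start=0, trim_end=0):
    """Exon intervals with exon ``index`` trimmed (positive values) or
    extended (negative values) at its transcript-orientation start/end."""
    exons = list(model.exons)
    s, e = exons[index - 1]
    if model.strand == "+":
        exons[index - 1] = (s + trim_start, e - trim_end)
    else:
        exons[index - 1] = (s + trim_end, e - trim_start)
    ns, ne = exons[index - 1]
    if ns > ne:
        raise GeneModelError("exon resized to non-positive length")
    return tuple(exons)


def _rank_sorted(candidates: list[SpliceOutcome]) -> list[SpliceOutcome]:
    """Order candidates by the frequency-based priority and assign ranks.

    Within cryptic kinds the nearest site comes first; equidistant ties put
    the exonic-side site (negative offset for donors, positive for
    acceptors... the caller encodes side in the sort key) first.
    """
    def key(oc: SpliceOutcome):
        off = abs(oc.site_offset) if oc.site_offset is not None else 0
        return (_KIND_PRIORITY[oc.kind], off, oc.delta_nt)

    ordered = sorted(candidates, key=key)
    return [
        SpliceOutcome(
            kind=oc.kind,
            modified_exons=oc.modified_exons,
            delta_nt=oc.delta_nt,
            rank=i,
            site_offset=oc.site_offset,
            description=oc.description,
        )
        for i, oc in enumerate(ordered, start=1)
    ]


def enumerate_outcomes(
    model: TranscriptModel,
    mutated_genome: GenomeSequence,
    classification: MutationClassification,
    params: ScanParams = ScanParams(),
    wildtype_model: Optional[TranscriptModel] = None,
) -> list[SpliceOutcome]:
    """Ranked candidate outcomes for a classified mutation.

    ESS donor loss on intron k proposes: skip of exon k, cryptic donors
    (exonic, upstream of the lost donor, and intronic, downstream of it),
    and retention of intron k when short or terminal.  ESS acceptor loss
    mirrors this on exon k+1; when exon k+1 is the terminal exon the skip
    is replaced by a no_rescue candidate.  Exonic nonsense proposes the
    PTC-bearing normally-spliced transcript and the nonsense-associated
    skip of the affected exon.  Exonic indels propose the normally-spliced
    (frameshifted) transcript only; see ``scan_exon_internal_acceptors``
    for the opt-in neighbouring-exon scan.

    Scan regions are clipped to the exon/intron flanking the lost site.
    """
    cat = classification.category
    if cat == "ESS_donor":
        k = classification.affected_intron_index
        assert k is not None
        return _rank_sorted(_donor_loss(model, mutated_genome, k, params))
    if cat == "ESS_acceptor":
        k = classification.affected_intron_index
        assert k is not None
        return _rank_sorted(_acceptor_loss(model, mutated_genome, k, params))
    if cat == "exonic_nonsense":
        k = classification.affected_exon_index
        assert k is not None
        candidates = [
            SpliceOutcome(
                "unspliced_ptc", model.exons, 0,
                description="PTC retained in normally spliced transcript",
            ),
            SpliceOutcome(
                "exon_skip", _strip_exon(model, k),
                -model.exon_lengths[k - 1],
                description=f"nonsense-associated skip of exon {k}",
            ),
        ]
        return [
            SpliceOutcome(c.kind, c.modified_exons, c.delta_nt, i,
                          c.site_offset, c.description)
            for i, c in enumerate(candidates, start=1)
        ]
    if cat in ("exonic_indel_frameshift", "exonic_indel_inframe"):
        # model/exons are expected in mutated (lifted) coordinates here;
        # delta_nt is measured against the wildtype model when supplied
        delta = (
            model.spliced_length - wildtype_model.spliced_length
            if wildtype_model is not None
            else 0
        )
        return [
            SpliceOutcome(
                "unspliced_ptc", model.exons, delta, 1,
                description="indel retained in normally spliced transcript",
            )
        ]
    raise MutationError(
        f"cannot enumerate splice outcomes for category {cat!r}"
    )


def _donor_loss(model, genome, k, params):
    exon_len = model.exon_lengths[k - 1]
    intron_len = model.intron_length(k)
    exon_seq = exon_sequence(model, genome, k)
    intron_seq = intron_sequence(model, genome, k)
    region = exon_seq + intron_seq
    anchor = exon_len + 1  # first base of the (lost) wildtype donor

    candidates = [
        SpliceOutcome(
            "exon_skip", _strip_exon(model, k), -exon_len,
            description=f"skip of exon {k}",
        )
    ]
    for offset, pos in scan_cryptic_sites(
        region, params.donor_motif, anchor, params.window_nt
    ):
        if pos <= exon_len:  # exonic cryptic donor: 3' truncation of exon k
            if pos < 2:
                continue
            trimmed = exon_len - pos + 1
            candidates.append(
                SpliceOutcome(
                    "cryptic_donor",
                    _resize_exon(model, k, trim_end=trimmed),
                    -trimmed,
                    site_offset=offset,
                    description=f"exonic cryptic donor, exon {k} 3' -{trimmed} nt",
                )
            )
        else:  # intronic cryptic donor: retains intron bases upstream of it
            q = pos - exon_len  # 1-based position within intron
            if q < 2 or q > intron_len - 3:
                continue
            retained = q - 1
            candidates.append(
                SpliceOutcome(
                    "cryptic_donor",
                    _resize_exon(model, k, trim_end=-retained),
                    retained,
                    site_offset=offset,
                    description=(
                        f"intronic cryptic donor, +{retained} nt of intron "
                        f"{k}-{k + 1} retained"
                    ),
                )
            )
    if intron_len <= params.intron_retention_max_nt or k == model.n_introns:
        candidates.append(
            SpliceOutcome(
                "intron_retention", _merge_intron(model, k), intron_len,
                description=f"retention of intron {k}-{k + 1}",
            )
        )
    return candidates


def _acceptor_loss(model, genome, k, params):
    intron_len = model.intron_length(k)
    exon_len = model.exon_lengths[k]  # exon k+1
    intron_seq = intron_sequence(model, genome, k)
    exon_seq = exon_sequence(model, genome, k + 1)
    region = intron_seq + exon_seq
    anchor = intron_len - 1  # first base of the (lost) wildtype acceptor AG

    terminal = (k + 1) == model.n_exons
    if terminal:
        candidates = [
            SpliceOutcome(
                "no_rescue", model.exons, 0,
                description=(
                    f"acceptor of terminal exon {k + 1} lost; no skip "
                    "candidate exists"
                ),
            )
        ]
    else:
        candidates = [
            SpliceOutcome(
                "exon_skip", _strip_exon(model, k + 1), -exon_len,
                description=f"skip of exon {k + 1}",
            )
        ]
    for offset, pos in scan_cryptic_sites(
        region, params.acceptor_motif, anchor, params.window_nt
    ):
        if pos <= intron_len:  # intronic cryptic acceptor upstream
            q = pos
            if q < 3 or q > intron_len - 3:
                continue
            retained = intron_len - q - 1
            candidates.append(
                SpliceOutcome(
                    "cryptic_acceptor",
                    _resize_exon(model, k + 1, trim_start=-retained),
                    retained,
                    site_offset=offset,
                    description=(
                        f"intronic cryptic acceptor, +{retained} nt of intron "
                        f"{k}-{k + 1} retained"
                    ),
                )
            )
        else:  # exonic cryptic acceptor downstream: 5' truncation
            p = pos - intron_len
            if p > exon_len - 2:
                continue
            trimmed = p + 1
            candidates.append(
                SpliceOutcome(
                    "cryptic_acceptor",
                    _resize_exon(model, k + 1, trim_start=trimmed),
                    -trimmed,
                    site_offset=offset,
                    description=(
                        f"exonic cryptic acceptor, exon {k + 1} 5' -{trimmed} nt"
                    ),
                )
            )
    if intron_len <= params.intron_retention_max_nt or k == model.n_introns:
        candidates.append(
            SpliceOutcome(
                "intron_retention", _merge_intron(model, k), intron_len,
                description=f"retention of intron {k}-{k + 1}",
            )
        )
    return candidates


def scan_exon_internal_acceptors(
    model: TranscriptModel,
    mutated_genome: GenomeSequence,
    exon_index: int,
    params: ScanParams = ScanParams(),
) -> list[SpliceOutcome]:
    """Cryptic acceptors *inside* an exon, downstream of its natural acceptor.

    This is the phenomenon seen at a neighbouring exon of an exonic
    deletion: internal AG dinucleotides act as alternative acceptors and
    produce 5'-truncated versions of the exon.  Each AG at exon positions
    (p, p+1) within the window yields a truncation of p+1 nt
    (delta_nt = -(p+1)).  Exposed as an explicit opt-in scan because the
    correlation with a distal lesion is observational, not mechanistic.
    """
    if not 1 <= exon_index <= model.n_exons:
        raise GeneModelError(f"exon index {exon_index} out of range")
    seq = exon_sequence(model, mutated_genome, exon_index)
    outcomes = []
    limit = min(params.window_nt, len(seq) - 2)
    for p in range(1, limit + 1):
        if seq[p - 1 : p + 1] == params.acceptor_motif:
            trunc = p + 1
            outcomes.append(
                SpliceOutcome(
                    "cryptic_acceptor",
                    _resize_exon(model, exon_index, trim_start=trunc),
                    -trunc,
                    site_offset=trunc,
                    description=(
                        f"internal cryptic acceptor, exon {exon_index} 5' "
                        f"-{trunc} nt"
                    ),
                )
            )
    return [
        SpliceOutcome(o.kind, o.modified_exons, o.delta_nt, i, o.site_offset,
                      o.description)
        for i, o in enumerate(outcomes, start=1)
    ]
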