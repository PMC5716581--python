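"""Genome sequences, transcript models and coordinate arithmetic.

All external coordinates are 1-based and inclusive (HGVS g. / GFF3
convention).  Exons of a :class:`TranscriptModel` are stored as genomic
intervals in *transcription order*, so "exon 2" always means the second
transcribed exon regardless of strand, and "intron k" lies between exons
k and k+1.  Spliced sequences, junction maps and intron sequences are
returned in transcript orientation (reverse-complemented for minus-strand
models), which is the orientation every downstream module works in.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

DONOR = "GT"
ACCEPTOR = "AG"


class GeneModelError(ValueError):
    """Raised for malformed sequences, annotations or coordinates."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomeSequence:
    """A set of named contigs holding uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise GeneModelError(f"contig {name!r} is empty")
            bad = set(seq) - ALPHABET
            if bad:
                raise GeneModelError(
                    f"contig {name!r} contains characters outside A/C/G/T/N: "
                    f"{sorted(bad)}"
                )

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``contig`` on [start, end], 1-based inclusive."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise GeneModelError(f"unknown contig {contig!r}") from None
        if not (1 <= start <= end <= len(seq)):
            raise GeneModelError(
                f"range {start}-{end} out of bounds for contig {contig!r} "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]

    def with_contig(self, name: str, seq: str) -> "GenomeSequence":
        new = dict(self.contigs)
        new[name] = seq
        return GenomeSequence(new)


@dataclass(frozen=True)
class JunctionMap:
    """Transcript-coordinate positions of the last base of each non-terminal exon."""

    junctions: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.junctions, self.junctions[1:])):
            raise GeneModelError("junction positions must be strictly increasing")

    @property
    def last(self) -> Optional[int]:
        return self.junctions[-1] if self.junctions else None

    def __len__(self) -> int:
        return len(self.junctions)


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript on a genomic contig.

    ``exons`` are (start, end) genomic intervals with start <= end, ordered in
    transcription order (ascending genomic coordinate on '+', descending on
    '-').  ``cds_start``/``cds_end`` are 1-based positions within the spliced
    mRNA; the wildtype coding span (cds_end - cds_start + 1) is expected to be
    divisible by 3.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise GeneModelError(f"{self.transcript_id}: transcript has no exons")
        for s, e in self.exons:
            if s > e:
                raise GeneModelError(f"{self.transcript_id}: exon {s}-{e} inverted")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.transcript_id}: overlapping exons")
            if s2 - e1 - 1 < 4:
                raise GeneModelError(
                    f"{self.transcript_id}: intron of length {s2 - e1 - 1} < 4"
                )
        expect = ordered if self.strand == "+" else ordered[::-1]
        if tuple(expect) != self.exons:
            raise GeneModelError(
                f"{self.transcript_id}: exons not in transcription order"
            )
        if not (1 <= self.cds_start <= self.cds_end <= self.spliced_length):
            raise GeneModelError(
                f"{self.transcript_id}: CDS {self.cds_start}-{self.cds_end} outside "
                f"spliced length {self.spliced_length}"
            )

    # -- basic geometry -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def genomic_span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def intron_interval(self, index: int) -> tuple[int, int]:
        """Genomic (start, end) of intron ``index`` (1-based, between exons
        index and index+1); start <= end regardless of strand."""
        if not 1 <= index <= self.n_introns:
            raise GeneModelError(
                f"intron index {index} out of range 1..{self.n_introns}"
            )
        a = self.exons[index - 1]
        b = self.exons[index]
        if self.strand == "+":
            return a[1] + 1, b[0] - 1
        return b[1] + 1, a[0] - 1

    def intron_length(self, index: int) -> int:
        s, e = self.intron_interval(index)
        return e - s + 1

    # -- coordinate mapping ---------------------------------------------

    def genomic_to_transcript(self, pos: int) -> Optional[int]:
        """Map a genomic position to its 1-based spliced-mRNA position, or
        None when the position falls in an intron or outside the transcript."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s + 1)
                return offset + (e - pos + 1)
            offset += e - s + 1
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 1 <= tpos <= self.spliced_length:
            raise GeneModelError(f"transcript position {tpos} out of range")
        offset = 0
        for s, e in self.exons:
            length = e - s + 1
            if tpos <= offset + length:
                within = tpos - offset
                return s + within - 1 if self.strand == "+" else e - within + 1
            offset += length
        raise AssertionError("unreachable")

    def exon_index_of(self, pos: int) -> Optional[int]:
        """1-based transcription-order index of the exon containing genomic
        ``pos``, or None."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def intron_index_of(self, pos: int) -> Optional[int]:
        for i in range(1, self.n_introns + 1):
            s, e = self.intron_interval(i)
            if s <= pos <= e:
                return i
        return None

    def intron_offset_from_donor(self, intron_index: int, pos: int) -> int:
        """1-based offset of genomic ``pos`` from the intron's first
        (donor-side) base, counted in transcript orientation."""
        s, e = self.intron_interval(intron_index)
        if not s <= pos <= e:
            raise GeneModelError(f"position {pos} not in intron {intron_index}")
        return pos - s + 1 if self.strand == "+" else e - pos + 1


# -- FASTA ---------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a (possibly gzipped) multi-record FASTA into a GenomeSequence.

    Record ids are truncated at the first whitespace; sequences are
    uppercased and validated against the A/C/G/T/N alphabet.
    """
    contigs: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in contigs:
                raise GeneModelError(f"duplicate contig id {record.id!r}")
            seq = str(record.seq).upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise GeneModelError(
                    f"record {record.id!r}: illegal character(s) {sorted(bad)}"
                )
            contigs[record.id] = seq
    if not contigs:
        raise GeneModelError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in genome.contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# -- annotation reading (GFF3 / GTF via gffutils) ------------------------


def _transcript_id_of(feature, dialect_gtf: bool) -> Optional[str]:
    if dialect_gtf:
        vals = feature.attributes.get("transcript_id")
    else:
        vals = feature.attributes.get("Parent")
    return vals[0] if vals else None


def read_annotation(
    path: str | Path, genome: Optional[GenomeSequence] = None
) -> list[TranscriptModel]:
    """Read transcript models from a GFF3 or GTF file (dialect auto-detected).

    Exons are grouped per transcript and sorted into transcription order;
    CDS features are converted to transcript coordinates.  Transcripts whose
    CDS is not contained in their exons raise; transcript features with no
    exons are skipped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    dialect_gtf = bool(db.dialect.get("fmt") == "gtf")

    gene_of: dict[str, str] = {}
    declared: list[str] = []
    for ftype in ("mRNA", "transcript"):
        for f in db.features_of_type(ftype):
            tid = f.id
            gid = (
                f.attributes.get("gene_id", [None])[0]
                or f.attributes.get("Parent", [None])[0]
                or tid
            )
            if dialect_gtf:
                tid = f.attributes.get("transcript_id", [tid])[0]
            gene_of[tid] = gid
            declared.append(tid)

    exons: dict[str, list[tuple[int, int, str, str]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    for f in db.features_of_type(("exon", "CDS")):
        tid = _transcript_id_of(f, dialect_gtf)
        if tid is None:
            logger.warning("feature at %s:%s-%s has no transcript; skipped",
                           f.seqid, f.start, f.end)
            continue
        if dialect_gtf and tid not in gene_of:
            gene_of[tid] = f.attributes.get("gene_id", [tid])[0]
        if f.featuretype == "exon":
            exons.setdefault(tid, []).append((f.start, f.end, f.seqid, f.strand))
        else:
            cdss.setdefault(tid, []).append((f.start, f.end))

    for tid in declared:
        if tid not in exons:
            logger.warning("transcript %s has no exons; skipped", tid)

    models = []
    for tid, parts in exons.items():
        contig = parts[0][2]
        strand = parts[0][3]
        ivals = sorted((s, e) for s, e, _, _ in parts)
        if strand == "-":
            ivals = ivals[::-1]
        model = TranscriptModel(
            gene_id=gene_of.get(tid, tid),
            transcript_id=tid,
            contig=contig,
            strand=strand,
            exons=tuple(ivals),
            cds_start=1,
            cds_end=sum(e - s + 1 for s, e in ivals),
        )
        if tid in cdss:
            tpos: list[int] = []
            for s, e in cdss[tid]:
                for g in (s, e):
                    t = model.genomic_to_transcript(g)
                    if t is None:
                        raise GeneModelError(
                            f"{tid}: CDS {s}-{e} not contained in exons"
                        )
                    tpos.append(t)
            model = replace(model, cds_start=min(tpos), cds_end=max(tpos))
        models.append(model)
    return models


def write_gff3(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models (mRNA, exon, CDS features) as GFF3."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for m in models:
            span = m.genomic_span
            out.write(
                "\t".join(
                    [m.contig, "splicefate", "mRNA", str(span[0]), str(span[1]),
                     ".", m.strand, ".",
                     f"ID={m.transcript_id};gene_id={m.gene_id}"]
                )
                + "\n"
            )
            for i, (s, e) in enumerate(m.exons, start=1):
                out.write(
                    "\t".join(
                        [m.contig, "splicefate", "exon", str(s), str(e), ".",
                         m.strand, ".",
                         f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}"]
                    )
                    + "\n"
                )
            # CDS genomic pieces, transcript order, with GFF3 phase
            coding = 0
            for i in range(1, m.n_exons + 1):
                piece = _cds_piece(m, i)
                if piece is None:
                    continue
                s, e = piece
                phase = (3 - coding % 3) % 3
                out.write(
                    "\t".join(
                        [m.contig, "splicefate", "CDS", str(s), str(e), ".",
                         m.strand, str(phase),
                         f"ID={m.transcript_id}.cds;Parent={m.transcript_id}"]
                    )
                    + "\n"
                )
                coding += e - s + 1


def _cds_piece(model: TranscriptModel, exon_index: int) -> Optional[tuple[int, int]]:
    """Genomic interval of the coding part of one exon, or None if non-coding."""
    offset = sum(model.exon_lengths[: exon_index - 1])
    length = model.exon_lengths[exon_index - 1]
    lo = max(model.cds_start, offset + 1)
    hi = min(model.cds_end, offset + length)
    if lo > hi:
        return None
    g1 = model.transcript_to_genomic(lo)
    g2 = model.transcript_to_genomic(hi)
    return (g1, g2) if g1 <= g2 else (g2, g1)


# -- spliced sequence ----------------------------------------------------


def exon_sequence(model: TranscriptModel, genome: GenomeSequence, index: int) -> str:
    """Transcript-oriented sequence of exon ``index`` (1-based)."""
    if not 1 <= index <= model.n_exons:
        raise GeneModelError(f"exon index {index} out of range 1..{model.n_exons}")
    s, e = model.exons[index - 1]
    seq = genome.fetch(model.contig, s, e)
    return seq if model.strand == "+" else reverse_complement(seq)


def spliced_sequence(
    model: TranscriptModel, genome: GenomeSequence
) -> tuple[str, JunctionMap]:
    """Mature mRNA (transcript orientation) and its exon-junction map."""
    parts = [exon_sequence(model, genome, i) for i in range(1, model.n_exons + 1)]
    junctions = []
    total = 0
    for p in parts[:-1]:
        total += len(p)
        junctions.append(total)
    return "".join(parts), JunctionMap(tuple(junctions))


def intron_sequence(
    model: TranscriptModel, genome: GenomeSequence, intron_index: int
) -> str:
    """Transcript-oriented sequence of intron ``intron_index``; starts with the
    donor dinucleotide and ends with the acceptor dinucleotide when canonical."""
    s, e = model.intron_interval(intron_index)
    seq = genome.fetch(model.contig, s, e)
    return seq if model.strand == "+" else reverse_complement(seq)


def validate_splice_sites(
    model: TranscriptModel, genome: GenomeSequence
) -> list[str]:
    """One warning string per intron whose donor is not GT or acceptor not AG."""
    warnings = []
    for i in range(1, model.n_introns + 1):
        seq = intron_sequence(model, genome, i)
        if seq[:2] != DONOR:
            warnings.append(
                f"intron {i}-{i + 1}: donor {seq[:2]!r} is not {DONOR}"
            )
        if seq[-2:] != ACCEPTOR:
            warnings.append(
                f"intron {i}-{i + 1}: acceptor {seq[-2:]!r} is not {ACCEPTOR}"
            )
    return warnings
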