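"""Shared builders for toy genomes and transcript models."""

import random

import pytest

from splicefate import GenomeSequence, TranscriptModel
from splicefate.genemodel import reverse_complement

STOPS = {"TAA", "TAG", "TGA"}


def make_genome(seq: str, name: str = "chr1") -> GenomeSequence:
    return GenomeSequence({name: seq.upper()})


def build_gene(
    exon_seqs: list[str],
    intron_seqs: list[str],
    flank5: str = "CCCCCCCCCC",
    flank3: str = "CCCCCCCCCC",
    utr5: int = 0,
    utr3: int = 0,
    strand: str = "+",
    contig: str = "chr1",
    transcript_id: str = "T1",
):
    """Assemble a plus-strand gene from explicit exon/intron sequences and
    optionally mirror it onto the minus strand."""
    assert len(intron_seqs) == len(exon_seqs) - 1
    pieces = [flank5]
    exons = []
    pos = len(flank5)
    for i, ex in enumerate(exon_seqs):
        exons.append((pos + 1, pos + len(ex)))
        pieces.append(ex)
        pos += len(ex)
        if i < len(intron_seqs):
            pieces.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    pieces.append(flank3)
    contig_seq = "".join(pieces)
    spliced = sum(len(e) for e in exon_seqs)
    model = TranscriptModel(
        gene_id="G1",
        transcript_id=transcript_id,
        contig=contig,
        strand="+",
        exons=tuple(exons),
        cds_start=utr5 + 1,
        cds_end=spliced - utr3,
    )
    genome = make_genome(contig_seq, contig)
    if strand == "-":
        return mirror(genome, model)
    return genome, model


def mirror(genome: GenomeSequence, model: TranscriptModel):
    """Reverse-complement the contig and flip the model's strand/coordinates;
    the spliced mRNA must be invariant under this transformation."""
    seq = genome.contigs[model.contig]
    L = len(seq)
    flipped = reverse_complement(seq)
    new_exons = tuple(
        (L - e + 1, L - s + 1) for s, e in model.exons
    )
    new_model = TranscriptModel(
        gene_id=model.gene_id,
        transcript_id=model.transcript_id,
        contig=model.contig,
        strand="-" if model.strand == "+" else "+",
        exons=new_exons,
        cds_start=model.cds_start,
        cds_end=model.cds_end,
    )
    return GenomeSequence({model.contig: flipped}), new_model


def random_cds(rng: random.Random, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if c not in STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def random_gene(rng: random.Random, n_exons: int = None, strand: str = "+"):
    """A random canonical gene: GT...AG introns, fully coding exons."""
    if n_exons is None:
        n_exons = rng.randint(2, 6)
    total_codons = rng.randint(n_exons * 4, n_exons * 20)
    cds = random_cds(rng, total_codons)
    cuts = sorted(rng.sample(range(1, len(cds)), n_exons - 1))
    bounds = [0] + cuts + [len(cds)]
    exon_seqs = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    intron_seqs = [
        "GT" + "".join(rng.choice("ACT") for _ in range(rng.randint(4, 30))) + "AG"
        for _ in range(n_exons - 1)
    ]
    flank = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
    flank2 = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 40)))
    return build_gene(exon_seqs, intron_seqs, flank, flank2, strand=strand)


@pytest.fixture
def rng():
    return random.Random(20180131)


@pytest.fixture(scope="session")
def mimics():
    from splicefate import all_mimics

    return all_mimics(seed=1)
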