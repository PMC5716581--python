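# Methods

## Scope and model

splicefate models one question: given a transcript model (exons, CDS,
strand) and a single genomic lesion, what mature mRNAs can plausibly be
produced, and what happens to each one's open reading frame?

The prediction chain is deliberately mechanical, mirroring how such
lesions are analyzed at the bench:

1. **Classification.** A substitution at intron position +1/+2
   (transcript orientation) is an ESS donor hit; −2/−1 an ESS acceptor
   hit. Exonic substitutions are compared codon-wise in the wildtype
   reading frame of the supplied transcript (no alternative-frame
   search); exonic deletions are frameshifting iff their length is not
   divisible by 3. Deletions that cross an exon boundary are rejected
   as unsupported — none of the characterized cases needs them.
2. **Outcome enumeration.** For an ESS loss the candidates are, in the
   field's frequency order: skip of the affected exon (the upstream
   exon for a donor loss, the downstream exon for an acceptor loss);
   cryptic-site use; intron retention. Candidates are ranked in that
   order, nearest cryptic site first, exonic side first on distance
   ties. When the acceptor of the *terminal* exon is lost no skip
   candidate exists; a `no_rescue` record takes its place. For an
   exonic nonsense mutation the candidates are the normally spliced
   PTC-bearing transcript (rank 1 — normal splicing is the default
   fate) and the nonsense-associated skip of the affected exon.
   Exonic indels yield only the normally spliced record; the
   internal-acceptor scan of a *neighbouring* exon (seen alongside an
   exonic deletion in one line) is an explicit opt-in
   (`scan_exon_internal_acceptors`, CLI `--neighbor-exon`), because the
   reported phenomenon is a correlation, not a mechanism.
   Pseudo-exon creation via intronic cryptic start sites is not
   enumerated; every report row carries a fixed
   "pseudo-exon not evaluated" flag instead.
3. **Consequence.** Each outcome's exon chain is spliced against the
   mutated genome; the CDS is re-mapped from the genomic anchor of the
   wildtype start codon (if an outcome removes the start codon the
   record is flagged `start-lost`; downstream-start rescue is out of
   scope). Translation uses the standard code. The first in-frame stop
   strictly upstream of where the wildtype stop maps is a PTC.
4. **NMD.** `escape` iff the PTC is downstream of the last exon–exon
   junction or within `escape_threshold_nt` upstream of it; `degraded`
   otherwise; single-exon transcripts always escape. The two published
   escape clauses ("in the last exon" and "within 50–55 nt of the last
   junction") collapse into this one predicate.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `ScanParams.window_nt` | 100 | nt | observed cryptic sites lie 2–40 nt from the lost site; 100 is generous yet keeps reports short |
| `ScanParams.intron_retention_max_nt` | 1000 | nt | retention is proposed for short introns; terminal introns always |
| `ScanParams.donor_motif` / `acceptor_motif` | GT / AG | — | candidate sites are motif matches only; no strength scoring (MaxEnt-style models are a non-goal) |
| `NmdParams.escape_threshold_nt` | 55 | nt | upper end of the published 50–55 nt range, so a junction-adjacent PTC is robustly an escape; values outside 50–55 warn |

Cryptic-site scan regions are clipped to the exon/intron flanking the
lost site (exonic upstream + intronic downstream for a donor; intronic
upstream + exonic downstream for an acceptor). This matches where a
replacement site can mechanistically act and keeps the canonical GT/AG
of neighbouring introns out of the candidate list. `site_offset` is
measured from the first base of the wildtype dinucleotide to the first
base of the cryptic one, signed, positive downstream. For an exonic
cryptic acceptor this offset numerically equals the truncation length,
because the wildtype AG sits exactly 2 nt before the exon.

Coordinates are 1-based inclusive everywhere a user sees them (HGVS g.
and GFF3 convention); exon numbering is 1-based in transcription order
regardless of strand. Minus-strand models are handled by orientation
normalization: exons are stored in transcription order and every
sequence handed to downstream modules is already reverse-complemented.
The fixtures are all plus-strand; minus-strand correctness is covered
by mirror-image property tests (reverse-complementing the contig and
flipping coordinates must leave the spliced mRNA, junction map and
mutation classification invariant).

Deletion handling lifts annotation coordinates onto the edited genome:
exon boundaries strictly downstream shift left by the deleted length,
and CDS transcript coordinates shrink when coding sequence is removed.

## Protein diffing

`diff_protein` decomposes wildtype vs mutant protein by longest common
prefix and suffix (suffix bounded so the two never overlap):
`aa_removed = len(wt) − lcp − lcs`, `aa_gained = len(mut) − lcp − lcs`,
and the excised residues are reported verbatim when at most 3 are lost.
The frame is `maintained` iff the common suffix covers everything after
the prefix on the shorter protein — i.e. the mutant realigns with the
wildtype downstream of the lesion. One consequence worth knowing: a
frameshifted tail that coincidentally ends in the same residue as the
wildtype absorbs that residue into the suffix, so `aa_removed` can be
smaller than a naive position-by-position count. A PTC-truncated but
otherwise identical protein is `maintained` (truncation is not a
frameshift).

`transcript_level_class` maps `degraded → reduced` and everything else
to `WT_like`, with one deliberate exception: a `no_rescue` outcome
(terminal-exon acceptor loss with no candidate isoform) is reported as
`reduced` with a caveat, since the transcript loss observed for such
alleles is presumed rather than derived from a PTC. Measured
fold-changes are wet-lab observations and are never predicted
quantitatively.

## ESE scanning

Scores are plain additive PWM sums (no log-odds transform); a window is
a hit iff `score ≥ threshold`, every window is evaluated, and windows
containing non-ACGT bases are skipped. A mutation is "in an ESE" when
any wildtype hit's window covers its position; "lost" hits are those
that drop below threshold in the mutant. No proprietary SRSF matrices
are shipped: the tab-delimited format accepts any PWM, and the bundled
`SYN_ESE1` matrix is synthetic (consensus `TACAACC`, 1/0 weights,
threshold 6.5 — one mismatch from consensus fails) for fixtures and
demonstrations only.

## Exon symmetry

Exon *i* of every transcript contributes its length mod 3 to index *i*
(up to index 10 by default). By default the full annotated exon length
(UTR included) is counted once per transcript, matching a
per-transcript feature dump; `--cds-only` switches to coding spans and
`--dedupe` counts identical exons of a gene once. Whether non-coding
transcripts of coding genes belong in the tally is genuinely ambiguous;
both modes exist and neither is asserted as canonical. The test is a
χ² goodness-of-fit against equal thirds: `Σ (Oᵢ − N/3)² / (N/3)`,
df = 2, p from the survival function (which for df = 2 is exactly
`exp(−x/2)`, a identity the tests pin to 1e-10). Text output prints
p-values below 2.2e-16 as `< 2.2e-16` by convention; JSON keeps the
exact float. `excess_r0` is `pct_r0 − 33.33` percentage points.

## Synthetic fixtures: what they emulate and what they do not

Each mimic reproduces the *structural* parameters of one characterized
line: exon counts and the critical exon lengths (116, 210, 114 nt), the
mutation's genomic coordinate (the 5' flank is sized so the published
g. position falls on the right base), the cryptic-site offsets (a
`TAG`-leading exon after an acceptor loss; a mutant intron beginning
`ATATGT`; internal exon AGs at 13/40 nt), a nonsense codon CAA→TAA
inside the planted ESE consensus, and a 7-nt exonic deletion. For the
terminal-junction escape case the engineered stop codon's first base
sits exactly on the last base of the penultimate exon (distance 0 nt to
the junction) — the only placement consistent with both the wildtype
phase-0 junction and the +4 frameshift.

Filler sequence is drawn from {A,C,T}: with no G outside planted
motifs, the only GT/AG dinucleotides in a fixture are the planted
splice and cryptic sites, so "no unintended nearer cryptic site" holds
by construction. The price is unrealistic base composition (no glycine
or tryptophan codons in filler regions, uncontrolled GC content), which
is irrelevant to the structural predictions under test but means the
fixtures say nothing about cryptic-site density in real sequence. Exact
mutant cDNA flanking sequence is not reproduced either, so
sequence-dependent published quantities (a 13-AA mutant ORF, 18 novel
residues) are deliberately not asserted — only their structural
counterparts (frameshift yes/no, PTC present, NMD class) are.

Stochastic requirements — a natural stop appearing in the shifted frame
more than the escape threshold upstream of the last junction, no
spurious ESE consensus hit in a 114-nt exon — are enforced by rejection
sampling: the builder re-draws filler from a salted sub-seed and
verifies every planted expectation through the real pipeline (not a
shortcut reimplementation) before returning, raising after 60 attempts
with advice to change seed. All randomness is integer-only draws from
`random.Random`, so fixtures are byte-identical across runs and
platforms for a given (name, seed).

Symmetry genomes draw each exon's remainder class on an integer grid of
10⁶ (again platform-stable): P(r = 0) = 1/3 + excess, the remaining
mass split evenly, then length = 3·U(20,100) + r. Transcripts default
to 2–8 exons — enough to exercise per-index tallies without pretending
to model real exon-count distributions.

## Problem sizes

The test suite and the acceptance script run on fixture transcripts of
0.5–3 kb (contigs up to ~65 kb, generated in memory), oracle sweeps of
1000 random sequences, a 200-replicate null calibration at ~300 index-2
exons per replicate, and planted-excess genomes of 20,000–50,000 exons
— sizes chosen so every study re-runs from scratch in seconds while
keeping binomial sampling error comfortably inside the asserted
tolerances (e.g. ±1.0 percentage point on a 38.43% recovery at
n = 25,000, where the standard error is ≈0.3 points).

## Known limitations

- Candidate cryptic sites are bare dinucleotide matches; no splice-site
  strength model, branch point or polypyrimidine tract is evaluated, so
  the enumeration over-proposes in real sequence (by design — the tool
  ranks *plausible* rescues for follow-up, it does not compute usage).
- Only single substitutions and simple deletions are supported; no
  insertions/duplications/delins, no compound alleles, no VCF input.
- One transcript isoform is analyzed at a time, and exon indices are
  meaningful only relative to the supplied `transcript_id`; no
  canonical-isoform guessing.
- Cryptic translation-start rescue and pseudo-exon creation are out of
  scope and surfaced only as caveat flags.
- NMD is a binary rule on one distance; efficiency, tissue variation
  and the 50–55 nt grey zone are not modelled beyond the configurable
  threshold.
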