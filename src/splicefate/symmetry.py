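"""Genome-wide exon mod-3 symmetry statistics.

An exon whose length is divisible by 3 is "symmetric": skipping it
preserves the reading frame, so a genome enriched for symmetric exons is
more permissive of exon-skip rescue.  This module tabulates the length
remainder (0, 1, 2) of exons at each transcription-order index across a
set of transcript models, tests each index against the uniform 1/3
expectation with a chi-squared goodness-of-fit test (df = 2), and
reports the excess of remainder-0 exons over the 33.33% chance level in
percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .genemodel import TranscriptModel

CHANCE_PCT = 33.33  # conventional printed chance level for one of three bins


@dataclass(frozen=True)
class IndexSummary:
    n_exons: int
    count_r0: int
    count_r1: int
    count_r2: int
    pct_r0: float
    pct_r1: float
    pct_r2: float
    chi2_stat: float
    p_value: float
    excess_r0: float


@dataclass(frozen=True)
class SymmetrySummary:
    per_exon_index: dict[int, IndexSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx in sorted(self.per_exon_index):
            s = self.per_exon_index[idx]
            rows.append(
                {
                    "exon_index": idx,
                    "n_exons": s.n_exons,
                    "count_r0": s.count_r0,
                    "count_r1": s.count_r1,
                    "count_r2": s.count_r2,
                    "pct_r0": s.pct_r0,
                    "pct_r1": s.pct_r1,
                    "pct_r2": s.pct_r2,
                    "chi2_stat": s.chi2_stat,
                    "p_value": s.p_value,
                    "p_value_text": format_p(s.p_value),
                    "excess_r0": s.excess_r0,
                }
            )
        return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """R-style convention: values below 2.2e-16 print as '< 2.2e-16'."""
    return "< 2.2e-16" if p < 2.2e-16 else f"{p:.4g}"


def chi_squared_uniform(counts) -> tuple[float, int, float]:
    """Chi-squared goodness-of-fit of three counts against equal thirds.

    statistic = sum((O_i - N/3)^2 / (N/3)); df = 2; p from the chi-squared
    survival function (for df = 2 this equals exp(-stat/2)).
    """
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3:
        raise ValueError("expected exactly three remainder counts")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("zero total count")
    stat, p = stats.chisquare(counts)
    return float(stat), 2, float(p)


def _exon_iter(models, cds_only: bool, dedupe: bool):
    """Yield (index, length) pairs, optionally restricting to coding spans
    and/or deduplicating identical exons across transcripts of one gene."""
    seen = set()
    for m in models:
        for i, (s, e) in enumerate(m.exons, start=1):
            if cds_only:
                offset = sum(m.exon_lengths[: i - 1])
                lo = max(m.cds_start, offset + 1)
                hi = min(m.cds_end, offset + m.exon_lengths[i - 1])
                if lo > hi:
                    continue
                length = hi - lo + 1
            else:
                length = e - s + 1
            if dedupe:
                key = (m.gene_id, i, s, e)
                if key in seen:
                    continue
                seen.add(key)
            yield i, length


def summarize_symmetry(
    models: list[TranscriptModel],
    max_index: int = 10,
    cds_only: bool = False,
    dedupe: bool = False,
) -> SymmetrySummary:
    """Per-exon-index remainder distribution over a set of transcripts.

    Exon i of each transcript contributes to index i when i <= max_index.
    By default the full annotated exon length (including UTR portions) is
    used, matching a per-transcript exon feature dump; ``cds_only``
    switches to coding spans and ``dedupe`` counts identical exons of one
    gene only once.
    """
    if not models:
        raise ValueError("no transcript models supplied")
    counts: dict[int, list[int]] = {}
    for idx, length in _exon_iter(models, cds_only, dedupe):
        if idx > max_index:
            continue
        counts.setdefault(idx, [0, 0, 0])[length % 3] += 1
    per_index = {}
    for idx, (r0, r1, r2) in counts.items():
        n = r0 + r1 + r2
        stat, _, p = chi_squared_uniform((r0, r1, r2))
        pct0 = 100.0 * r0 / n
        per_index[idx] = IndexSummary(
            n_exons=n,
            count_r0=r0,
            count_r1=r1,
            count_r2=r2,
            pct_r0=pct0,
            pct_r1=100.0 * r1 / n,
            pct_r2=100.0 * r2 / n,
            chi2_stat=stat,
            p_value=p,
            excess_r0=pct0 - CHANCE_PCT,
        )
    return SymmetrySummary(per_index)


def excess_over_chance(summary: SymmetrySummary, index: int) -> float:
    """Percentage points of remainder-0 exons above the 33.33% chance level."""
    if index not in summary.per_exon_index:
        raise KeyError(f"no exons summarized at index {index}")
    return summary.per_exon_index[index].excess_r0
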