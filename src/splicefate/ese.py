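"""Exonic splice enhancer (ESE) scanning with position-weight matrices.

A nonsense mutation can do more than truncate a protein: when it falls
inside an ESE it weakens exon definition and can trigger skipping of the
affected exon (nonsense-associated splicing).  This module scores exonic
sequence against user-supplied PWMs with a simple additive score and a
per-matrix hit threshold (hit iff score >= threshold), and flags
mutations whose position is covered by a wildtype hit.

No proprietary SRSF matrices are shipped; the file format accepts any
PWM and the bundled demonstration matrix is synthetic, with a known
consensus, for fixtures and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

_BASES = "ACGT"


class EseError(ValueError):
    pass


@dataclass(frozen=True)
class EseMatrix:
    """Additive PWM: weights[i][b] scores base b at motif position i."""

    name: str
    weights: tuple[tuple[float, float, float, float], ...]  # A, C, G, T
    threshold: float

    def __post_init__(self) -> None:
        if len(self.weights) < 4:
            raise EseError(f"matrix {self.name!r}: length must be >= 4")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def consensus(self) -> str:
        return "".join(
            _BASES[max(range(4), key=lambda b: row[b])] for row in self.weights
        )

    def score(self, window: str) -> float | None:
        """Additive score of a window of matrix length; None when the
        window holds a base outside A/C/G/T (e.g. N)."""
        total = 0.0
        for row, base in zip(self.weights, window):
            idx = _BASES.find(base)
            if idx == -1:
                return None
            total += row[idx]
        return total


@dataclass(frozen=True)
class EseHit:
    matrix_name: str
    start: int  # 1-based offset in the scanned sequence
    score: float

    def covers(self, offset: int, length: int) -> bool:
        return self.start <= offset <= self.start + length - 1


# A synthetic demonstration matrix (consensus TACAACC, 1/0 weights): real
# analyses should load published matrices via --ese-matrices.
DEMO_MATRIX = EseMatrix(
    name="SYN_ESE1",
    weights=tuple(
        tuple(1.0 if b == base else 0.0 for b in _BASES)
        for base in "TACAACC"
    ),
    threshold=6.5,
)


def load_matrices(path: str | Path) -> list[EseMatrix]:
    """Read PWMs from a tab-delimited file.

    Format per matrix: a header line ``>name<TAB>threshold`` followed by L
    rows of four scores in A, C, G, T order.  Several matrices may follow
    each other in one file.
    """
    matrices: list[EseMatrix] = []
    name = None
    threshold = None
    rows: list[tuple[float, float, float, float]] = []

    def flush(lineno):
        nonlocal name, threshold, rows
        if name is None:
            return
        if threshold is None:
            raise EseError(f"line {lineno}: matrix {name!r} missing threshold")
        matrices.append(EseMatrix(name, tuple(rows), threshold))
        name, threshold, rows = None, None, []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split("\t")
                if len(fields) != 2:
                    raise EseError(
                        f"line {lineno}: header must be '>name<TAB>threshold'"
                    )
                name = fields[0]
                try:
                    threshold = float(fields[1])
                except ValueError:
                    raise EseError(
                        f"line {lineno}: bad threshold {fields[1]!r}"
                    ) from None
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise EseError(
                    f"line {lineno}: expected 4 tab-separated scores, got "
                    f"{len(fields)}"
                )
            if name is None:
                raise EseError(f"line {lineno}: scores before any matrix header")
            try:
                rows.append(tuple(float(f) for f in fields))
            except ValueError:
                raise EseError(f"line {lineno}: non-numeric score") from None
    flush("EOF")
    if not matrices:
        raise EseError(f"no matrices found in {path}")
    return matrices


def write_matrices(matrices: list[EseMatrix], path: str | Path) -> None:
    with open(path, "w") as out:
        for m in matrices:
            out.write(f">{m.name}\t{m.threshold}\n")
            for row in m.weights:
                out.write("\t".join(str(v) for v in row) + "\n")


def scan_ese(sequence: str, matrices: list[EseMatrix]) -> list[EseHit]:
    """Score every window of every matrix; record hits with score >= threshold.

    Windows containing non-ACGT characters are skipped.  Output is ordered
    by start position then matrix name, independent of matrix order.
    """
    hits = []
    for m in matrices:
        L = len(m)
        for start in range(1, len(sequence) - L + 2):
            score = m.score(sequence[start - 1 : start - 1 + L])
            if score is not None and score >= m.threshold:
                hits.append(EseHit(m.name, start, score))
    hits.sort(key=lambda h: (h.start, h.matrix_name))
    return hits


def mutation_in_ese(
    exon_seq_wt: str,
    exon_seq_mut: str,
    mutation_offset: int,
    matrices: list[EseMatrix],
) -> tuple[bool, list[EseHit]]:
    """Does a single-base exonic change fall inside a predicted ESE?

    Returns (in_ese, lost_hits): in_ese is true when any wildtype hit's
    window covers ``mutation_offset`` (1-based in the exon); lost_hits are
    those covering hits whose window drops below the matrix threshold in
    the mutant sequence.
    """
    if len(exon_seq_wt) != len(exon_seq_mut):
        raise EseError("wildtype and mutant exon sequences differ in length")
    diffs = [
        i + 1
        for i, (a, b) in enumerate(zip(exon_seq_wt, exon_seq_mut))
        if a != b
    ]
    if diffs != [mutation_offset]:
        raise EseError(
            f"sequences must differ exactly at offset {mutation_offset}, "
            f"found differences at {diffs}"
        )
    by_name = {m.name: m for m in matrices}
    covering = [
        h
        for h in scan_ese(exon_seq_wt, matrices)
        if h.covers(mutation_offset, len(by_name[h.matrix_name]))
    ]
    lost = []
    for h in covering:
        m = by_name[h.matrix_name]
        window = exon_seq_mut[h.start - 1 : h.start - 1 + len(m)]
        mut_score = m.score(window)
        if mut_score is None or mut_score < m.threshold:
            lost.append(h)
    return bool(covering), lost
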