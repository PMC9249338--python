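"""Six-frame pseudogene translation and EMBOSS-NEEDLE-style global alignment.

The rescue question: how closely does the best translated product of a
pseudogene match the wild-type protein?  Each of the six reading frames
(three forward, three on the reverse complement, internal stops rendered '*')
is aligned globally to the reference; the frame with the highest alignment
score wins, and the alignment's identity / similarity / gap percentages are
reported with the EMBOSS definitions:

    identity   = 100 * identical columns / alignment length
    similarity = 100 * columns scoring > 0 under the matrix / length
    gaps       = 100 * columns with a gap in either row / length

Alignment is Needleman-Wunsch with affine gaps in the EMBOSS parameterisation
(gap open charged at the first gap column, extend per additional column;
defaults open 10.0 / extend 0.5 / BLOSUM62 / end gaps free) and a fixed
traceback tie-break: diagonal, then up (gap in the second sequence), then
left.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .genemodel import STANDARD_CODE, Sequence, translate_cds

__all__ = [
    "SubstitutionMatrix",
    "PairwiseAlignment",
    "PseudogeneReport",
    "blosum62",
    "six_frame_translate",
    "needleman_wunsch_align",
    "alignment_stats",
    "pseudogene_rescue_report",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue substitution scoring table."""

    name: str
    alphabet: str
    scores: dict[tuple[str, str], float]

    def score(self, a: str, b: str) -> float:
        try:
            return self.scores[(a, b)]
        except KeyError:
            raise KeyError(
                f"symbol pair ({a!r}, {b!r}) outside the {self.name} alphabet"
            ) from None


@lru_cache(maxsize=None)
def blosum62() -> SubstitutionMatrix:
    """BLOSUM62 with ambiguity 'X' and stop '*' columns (NCBI convention:
    '*' scores +1 against itself and -4 against everything else)."""
    m = substitution_matrices.load("BLOSUM62")
    alphabet = str(m.alphabet)
    scores = {
        (a, b): float(m[a, b]) for a in alphabet for b in alphabet
    }
    return SubstitutionMatrix("BLOSUM62", alphabet, scores)


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    gaps_pct: float

    @property
    def length(self) -> int:
        return len(self.aligned_a)

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@dataclass(frozen=True)
class PseudogeneReport:
    pseudogene_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse complement
    translated: str
    alignment: PairwiseAlignment
    diff_positions: list[int]  # 1-based ungapped reference residue indices
    internal_stops: int


def six_frame_translate(dna: Sequence | str) -> dict[int, str]:
    """All six conceptual translations, keyed +1,+2,+3,-1,-2,-3.

    Internal stops are rendered '*' (no truncation); trailing partial codons
    are dropped.
    """
    seq = dna.residues if isinstance(dna, Sequence) else str(dna).upper()
    if len(seq) < 3:
        raise ValueError("need at least one full codon")
    rc = str(Seq(seq).reverse_complement())
    frames: dict[int, str] = {}
    for offset in range(3):
        fwd = seq[offset:]
        rev = rc[offset:]
        if len(fwd) >= 3:
            frames[offset + 1] = translate_cds(
                fwd, STANDARD_CODE, stop_at_first_stop=False
            )[0]
        if len(rev) >= 3:
            frames[-(offset + 1)] = translate_cds(
                rev, STANDARD_CODE, stop_at_first_stop=False
            )[0]
    return frames


def _validate_symbols(seq: str, matrix: SubstitutionMatrix) -> None:
    bad = set(seq) - set(matrix.alphabet)
    if bad:
        raise ValueError(
            f"symbols {sorted(bad)} outside the {matrix.name} alphabet"
        )


def needleman_wunsch_align(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    end_gaps_free: bool = True,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties (Gotoh).

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``; terminal
    gaps are free when ``end_gaps_free``.  Traceback ties break diagonal,
    then up (gap in b), then left (gap in a).
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    matrix = matrix or blosum62()
    _validate_symbols(a, matrix)
    _validate_symbols(b, matrix)

    n, m = len(a), len(b)
    sub = np.empty((n, m))
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            sub[i, j] = matrix.score(ca, cb)

    # M: a[i] aligned to b[j]; Ix: gap in b (move up, consume a);
    # Iy: gap in a (move left, consume b).  Index [i, j] = prefixes a[:i], b[:j].
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)
    Iy = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = (
            0.0 if end_gaps_free else -(gap_open + (i - 1) * gap_extend)
        )
    for j in range(1, m + 1):
        Iy[0, j] = (
            0.0 if end_gaps_free else -(gap_open + (j - 1) * gap_extend)
        )

    for i in range(1, n + 1):
        si = sub[i - 1]
        for j in range(1, m + 1):
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + si[j - 1]
            # trailing gaps (last column for Ix, last row for Iy) are free
            ogx = 0.0 if (end_gaps_free and j == m) else gap_open
            egx = 0.0 if (end_gaps_free and j == m) else gap_extend
            Ix[i, j] = max(M[i - 1, j] - ogx, Ix[i - 1, j] - egx, Iy[i - 1, j] - ogx)
            ogy = 0.0 if (end_gaps_free and i == n) else gap_open
            egy = 0.0 if (end_gaps_free and i == n) else gap_extend
            Iy[i, j] = max(M[i, j - 1] - ogy, Iy[i, j - 1] - egy, Ix[i, j - 1] - ogy)

    score = max(M[n, m], Ix[n, m], Iy[n, m])

    # Traceback, preferring diagonal > up > left at every tie.
    tol = 1e-9
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    if M[n, m] >= score - tol:
        state = "M"
    elif Ix[n, m] >= score - tol:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - target) < tol:
                state = "M"
            elif abs(Ix[i, j] - target) < tol:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            if j == 0:
                i -= 1  # leading gap column
                continue
            ogx = 0.0 if (end_gaps_free and j == m) else gap_open
            egx = 0.0 if (end_gaps_free and j == m) else gap_extend
            cur = Ix[i, j]
            if abs(M[i - 1, j] - ogx - cur) < tol:
                state = "M"
            elif abs(Ix[i - 1, j] - egx - cur) < tol:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:  # Y
            out_a.append("-")
            out_b.append(b[j - 1])
            if i == 0:
                j -= 1  # leading gap column
                continue
            ogy = 0.0 if (end_gaps_free and i == n) else gap_open
            egy = 0.0 if (end_gaps_free and i == n) else gap_extend
            cur = Iy[i, j]
            if abs(M[i, j - 1] - ogy - cur) < tol:
                state = "M"
            elif abs(Iy[i, j - 1] - egy - cur) < tol:
                state = "Y"
            else:
                state = "X"
            j -= 1

    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    ident, simil, gaps = alignment_stats(aligned_a, aligned_b, matrix)
    return PairwiseAlignment(aligned_a, aligned_b, float(score), ident, simil, gaps)


def alignment_stats(
    aligned_a: str, aligned_b: str, matrix: SubstitutionMatrix | None = None
) -> tuple[float, float, float]:
    """EMBOSS identity / similarity / gaps percentages for one alignment."""
    matrix = matrix or blosum62()
    if len(aligned_a) != len(aligned_b) or not aligned_a:
        raise ValueError("alignment rows must be nonempty and equal length")
    length = len(aligned_a)
    ident = simil = gaps = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        if ca == cb:
            ident += 1
        if matrix.score(ca, cb) > 0:
            simil += 1
    return (
        100.0 * ident / length,
        100.0 * simil / length,
        100.0 * gaps / length,
    )


def _diff_positions(aligned_ref: str, aligned_other: str) -> list[int]:
    """1-based reference residue indices whose aligned column differs."""
    diffs = []
    ref_i = 0
    for cr, co in zip(aligned_ref, aligned_other):
        if cr == "-":
            continue
        ref_i += 1
        if co != cr:
            diffs.append(ref_i)
    return diffs


def pseudogene_rescue_report(
    pseudogene: Sequence,
    reference_protein: Sequence | str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PseudogeneReport:
    """Best-frame alignment of a pseudogene's translation to the reference.

    All six frames are aligned; the highest-scoring frame wins (ties go to
    the frame earliest in the order +1, +2, +3, -1, -2, -3).
    """
    ref = (
        reference_protein.residues
        if isinstance(reference_protein, Sequence)
        else str(reference_protein)
    )
    frames = six_frame_translate(pseudogene)
    best_frame = None
    best_aln = None
    for frame in (1, 2, 3, -1, -2, -3):
        if frame not in frames:
            continue
        aln = needleman_wunsch_align(
            ref, frames[frame], matrix, gap_open, gap_extend
        )
        if best_aln is None or aln.score > best_aln.score:
            best_frame, best_aln = frame, aln
    assert best_frame is not None and best_aln is not None
    translated = frames[best_frame]
    return PseudogeneReport(
        pseudogene_id=pseudogene.id,
        frame=best_frame,
        translated=translated,
        alignment=best_aln,
        diff_positions=_diff_positions(best_aln.aligned_a, best_aln.aligned_b),
        internal_stops=translated.rstrip("*").count("*"),
    )
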