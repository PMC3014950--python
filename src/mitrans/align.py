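"""Affine-gap global pairwise alignment (Needleman-Wunsch / Gotoh).

The three-state Gotoh recursion with a fixed, documented traceback tie-break
(substitution preferred over a gap in the second row, preferred over a gap in
the first row) so that alignments — and everything derived from them — are
bit-reproducible.  An optional band restricts the dynamic program to a
diagonal corridor for long, largely collinear sequences; an optional
free-end-gap mode leaves terminal gaps unpenalised.

External alignments (from any global aligner) can be imported from two-record
gapped FASTA and are validated against the ungapped sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import NucleotideSequence, read_fasta

GAP = "-"
_CODE = {c: i for i, c in enumerate("ACGT")}

# predecessor-state codes packed in the pointer matrix
_M, _IX, _IY, _NONE = 0, 1, 2, 3
_NEG = -1e30


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch rewards and affine gap penalties (gap_open is the cost
    of the first gapped position, gap_extend of each further one)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("require gap_open <= gap_extend <= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped rows; no column is a gap in both rows."""

    x_aligned: str
    y_aligned: str
    x_id: str = "x"
    y_id: str = "y"
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.x_aligned) != len(self.y_aligned):
            raise ValueError("aligned rows differ in length")
        if not self.x_aligned:
            raise ValueError("empty alignment")
        for a, b in zip(self.x_aligned, self.y_aligned):
            if a == GAP and b == GAP:
                raise ValueError("all-gap column in alignment")

    def __len__(self) -> int:
        return len(self.x_aligned)

    @property
    def x_degapped(self) -> str:
        return self.x_aligned.replace(GAP, "")

    @property
    def y_degapped(self) -> str:
        return self.y_aligned.replace(GAP, "")

    def reversed(self) -> "PairwiseAlignment":
        """Swap the two rows (x becomes y)."""
        return PairwiseAlignment(
            self.y_aligned, self.x_aligned, self.y_id, self.x_id, self.score
        )


def as_alignment(x: NucleotideSequence, y: NucleotideSequence) -> PairwiseAlignment:
    """Positional (gap-free) alignment of two equal-length sequences.

    Valid whenever sites correspond one-to-one, e.g. for simulated evolution
    without indels.
    """
    if len(x.letters) != len(y.letters):
        raise ValueError("positional alignment requires equal lengths")
    return PairwiseAlignment(x.letters, y.letters, x.id, y.id)


@njit(cache=True)
def _gotoh_fill(xi, yi, match, mismatch, go, ge, band, free_end):  # pragma: no cover
    m, n = xi.size, yi.size
    ptr = np.full((3, m + 1, n + 1), _NONE, dtype=np.uint8)
    prevM = np.full(n + 1, _NEG)
    prevX = np.full(n + 1, _NEG)
    prevY = np.full(n + 1, _NEG)
    curM = np.full(n + 1, _NEG)
    curX = np.full(n + 1, _NEG)
    curY = np.full(n + 1, _NEG)

    prevM[0] = 0.0
    for j in range(1, n + 1):
        if band >= 0 and j > band + abs(m - n):
            break
        prevY[j] = 0.0 if free_end else (go + ge * (j - 1))
        ptr[_IY, 0, j] = _IY if j > 1 else _M

    for i in range(1, m + 1):
        for j in range(n + 1):
            curM[j] = _NEG
            curX[j] = _NEG
            curY[j] = _NEG
        lo, hi = 0, n
        if band >= 0:
            c = (i * n) // m
            lo = max(0, c - band)
            hi = min(n, c + band)
        if lo == 0:
            curX[0] = 0.0 if free_end else (go + ge * (i - 1))
            ptr[_IX, i, 0] = _IX if i > 1 else _M
        for j in range(max(lo, 1), hi + 1):
            a = xi[i - 1]
            b = yi[j - 1]
            s = match if a == b else mismatch
            # substitution state: tie-break M > IX > IY
            vm = prevM[j - 1]
            vx = prevX[j - 1]
            vy = prevY[j - 1]
            if vm >= vx and vm >= vy:
                curM[j] = vm + s
                ptr[_M, i, j] = _M
            elif vx >= vy:
                curM[j] = vx + s
                ptr[_M, i, j] = _IX
            else:
                curM[j] = vy + s
                ptr[_M, i, j] = _IY
            # gap in y row (consumes x): from row i-1, same j
            vm = prevM[j] + go
            vx = prevX[j] + ge
            vy = prevY[j] + go
            if vm >= vx and vm >= vy:
                curX[j] = vm
                ptr[_IX, i, j] = _M
            elif vx >= vy:
                curX[j] = vx
                ptr[_IX, i, j] = _IX
            else:
                curX[j] = vy
                ptr[_IX, i, j] = _IY
            # gap in x row (consumes y): from same row, j-1
            vm = curM[j - 1] + go
            vx = curX[j - 1] + go
            vy = curY[j - 1] + ge
            if vm >= vx and vm >= vy:
                curY[j] = vm
                ptr[_IY, i, j] = _M
            elif vx >= vy:
                curY[j] = vx
                ptr[_IY, i, j] = _IX
            else:
                curY[j] = vy
                ptr[_IY, i, j] = _IY
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY

    # final row is in prev*
    return ptr, prevM, prevX, prevY


@njit(cache=True)
def _gotoh_free_end_cols(xi, yi, match, mismatch, go, ge):  # pragma: no cover
    """Free-end-gap fill that also records the best score over the last row
    and last column.  Returns (ptr, i, j, state, score) of the traceback
    start before the unpenalised terminal gaps."""
    m, n = xi.size, yi.size
    ptr = np.full((3, m + 1, n + 1), _NONE, dtype=np.uint8)
    lastcol = np.full((3, m + 1), _NEG)
    prevM = np.full(n + 1, _NEG)
    prevX = np.full(n + 1, _NEG)
    prevY = np.full(n + 1, _NEG)
    curM = np.full(n + 1, _NEG)
    curX = np.full(n + 1, _NEG)
    curY = np.full(n + 1, _NEG)
    prevM[0] = 0.0
    for j in range(1, n + 1):
        prevY[j] = 0.0
        ptr[_IY, 0, j] = _IY if j > 1 else _M
    lastcol[_M, 0] = _NEG
    for i in range(1, m + 1):
        for j in range(n + 1):
            curM[j] = _NEG
            curX[j] = _NEG
            curY[j] = _NEG
        curX[0] = 0.0
        ptr[_IX, i, 0] = _IX if i > 1 else _M
        for j in range(1, n + 1):
            a = xi[i - 1]
            b = yi[j - 1]
            s = match if a == b else mismatch
            vm, vx, vy = prevM[j - 1], prevX[j - 1], prevY[j - 1]
            if vm >= vx and vm >= vy:
                curM[j] = vm + s
                ptr[_M, i, j] = _M
            elif vx >= vy:
                curM[j] = vx + s
                ptr[_M, i, j] = _IX
            else:
                curM[j] = vy + s
                ptr[_M, i, j] = _IY
            vm, vx, vy = prevM[j] + go, prevX[j] + ge, prevY[j] + go
            if vm >= vx and vm >= vy:
                curX[j] = vm
                ptr[_IX, i, j] = _M
            elif vx >= vy:
                curX[j] = vx
                ptr[_IX, i, j] = _IX
            else:
                curX[j] = vy
                ptr[_IX, i, j] = _IY
            vm, vx, vy = curM[j - 1] + go, curX[j - 1] + go, curY[j - 1] + ge
            if vm >= vx and vm >= vy:
                curY[j] = vm
                ptr[_IY, i, j] = _M
            elif vx >= vy:
                curY[j] = vx
                ptr[_IY, i, j] = _IX
            else:
                curY[j] = vy
                ptr[_IY, i, j] = _IY
        lastcol[_M, i] = curM[n]
        lastcol[_IX, i] = curX[n]
        lastcol[_IY, i] = curY[n]
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
    # best over last row (i = m) and last column (j = n); tie-break prefers
    # the full corner, then later cells, state order M > IX > IY
    bi, bj, bstate = m, n, _M
    bscore = prevM[n]
    for s_ in (_M, _IX, _IY):
        v = prevM[n] if s_ == _M else (prevX[n] if s_ == _IX else prevY[n])
        if v > bscore:
            bscore, bi, bj, bstate = v, m, n, s_
    for j in range(n, -1, -1):
        for s_ in (_M, _IX, _IY):
            vv = prevM[j] if s_ == _M else (prevX[j] if s_ == _IX else prevY[j])
            if vv > bscore:
                bscore, bi, bj, bstate = vv, m, j, s_
    for i in range(m, -1, -1):
        for s_ in (_M, _IX, _IY):
            vv = lastcol[s_, i]
            if vv > bscore:
                bscore, bi, bj, bstate = vv, i, n, s_
    return ptr, bi, bj, bstate, bscore


def _encode(letters: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE[c] for c in letters), dtype=np.int8, count=len(letters))
    except KeyError as exc:  # pragma: no cover - guarded upstream by clean()
        raise ValueError(f"non-ACGT letter {exc} in sequence") from exc


def global_align(
    x: NucleotideSequence,
    y: NucleotideSequence,
    scoring: ScoringScheme | None = None,
    band: int | None = None,
    free_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Score-maximal affine-gap global alignment of two cleaned sequences.

    ``band`` restricts the DP to a corridor of half-width ``band`` around the
    straight-line diagonal (exact mode when None).  Deterministic: ties are
    broken substitution > gap-in-y > gap-in-x throughout.
    """
    s = scoring or ScoringScheme()
    if not x.letters or not y.letters:
        raise ValueError("cannot align empty sequences")
    xi, yi = _encode(x.letters), _encode(y.letters)
    m, n = xi.size, yi.size

    if free_end_gaps:
        ptr, bi, bj, bstate, score = _gotoh_free_end_cols(
            xi, yi, float(s.match), float(s.mismatch),
            float(s.gap_open), float(s.gap_extend),
        )
        tail_x = x.letters[bi:]
        tail_y = y.letters[bj:]
        i, j, state = bi, bj, bstate
    else:
        bw = -1 if band is None else int(band)
        ptr, rowM, rowX, rowY = _gotoh_fill(
            xi, yi, float(s.match), float(s.mismatch),
            float(s.gap_open), float(s.gap_extend), bw, False,
        )
        finals = (rowM[n], rowX[n], rowY[n])
        state = int(np.argmax(finals))  # argmax keeps first max: M > IX > IY
        score = finals[state]
        if score <= _NEG / 2:
            raise ValueError("band too narrow: no alignment inside corridor")
        tail_x = tail_y = ""
        i, j = m, n

    xa: list[str] = []
    ya: list[str] = []
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            xa.append(x.letters[i - 1])
            ya.append(y.letters[j - 1])
            i -= 1
            j -= 1
        elif state == _IX:
            xa.append(x.letters[i - 1])
            ya.append(GAP)
            i -= 1
        else:
            xa.append(GAP)
            ya.append(y.letters[j - 1])
            j -= 1
        state = prev

    xrow = "".join(reversed(xa))
    yrow = "".join(reversed(ya))
    if free_end_gaps:
        xrow = xrow + tail_x + GAP * len(tail_y)
        yrow = yrow + GAP * len(tail_x) + tail_y
    return PairwiseAlignment(xrow, yrow, x.id, y.id, score=float(score))


def alignment_score(aln: PairwiseAlignment, scoring: ScoringScheme | None = None) -> float:
    """Recompute the affine-gap score of an alignment (end gaps penalised)."""
    s = scoring or ScoringScheme()
    total = 0.0
    in_gap_x = in_gap_y = False
    for a, b in zip(aln.x_aligned, aln.y_aligned):
        if a == GAP:
            total += s.gap_extend if in_gap_x else s.gap_open
            in_gap_x, in_gap_y = True, False
        elif b == GAP:
            total += s.gap_extend if in_gap_y else s.gap_open
            in_gap_x, in_gap_y = False, True
        else:
            total += s.match if a == b else s.mismatch
            in_gap_x = in_gap_y = False
    return total


def import_alignment(
    path, x: NucleotideSequence, y: NucleotideSequence
) -> PairwiseAlignment:
    """Load a two-record gapped FASTA and validate it against x and y."""
    recs = read_fasta(path)
    if len(recs) != 2:
        raise ValueError(f"expected exactly 2 aligned records, got {len(recs)}")
    ax, ay = recs[0].letters, recs[1].letters
    if len(ax) != len(ay):
        raise ValueError("aligned rows have unequal length")
    aln = PairwiseAlignment(ax, ay, x.id, y.id)  # also rejects all-gap columns
    if aln.x_degapped != x.letters or aln.y_degapped != y.letters:
        raise ValueError("alignment/sequence inconsistency: degapped rows differ")
    return aln


def write_alignment(aln: PairwiseAlignment, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, row in ((aln.x_id, aln.x_aligned), (aln.y_id, aln.y_aligned)):
            fh.write(f">{name}\n")
            for k in range(0, len(row), width):
                fh.write(row[k : k + width] + "\n")
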