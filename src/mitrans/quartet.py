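"""Quartet topology inference via the four-point condition.

For four taxa {a,b,c,d} the three pairings give sums

    s(ab|cd) = d(a,b) + d(c,d),  s(ac|bd), s(ad|bc);

an additive (tree) metric makes the two largest sums equal, the split with
the smallest sum is the tree topology, (s2 − s1)/2 estimates the internal
branch and s3 − s2 measures how far the data are from additivity.  A
significance score combines the two: calls with a long internal edge and a
small four-point violation are trustworthy.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

#: the three pairings of indices {0,1,2,3}, lexicographic order
SPLITS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))

#: regulariser weight in the significance score
SIGMA_REGULARIZER = 0.01

#: relative tolerance of the triangle-inequality audit
TRIANGLE_TOL = 1e-9


@dataclass(frozen=True)
class QuartetResult:
    taxa: tuple[str, str, str, str]
    sums: tuple[float, float, float]  # sorted s1 <= s2 <= s3
    split: tuple[tuple[int, int], tuple[int, int]]  # pairing attaining s1
    internal_edge: float  # (s2 - s1) / 2
    violation: float  # s3 - s2
    sigma: float = math.nan

    def newick(self) -> str:
        (i, j), (k, l) = self.split
        t = self.taxa
        return f"(({t[i]},{t[j]}),({t[k]},{t[l]}));"


def quartet_topology(d: np.ndarray, taxa=None) -> QuartetResult:
    """Call the topology of one quartet from its 4x4 distance matrix.

    Requires finite entries (an infinite distance makes the quartet
    unresolvable and raises).  Equal sums are broken toward the
    lexicographically smallest split, deterministically.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (4, 4):
        raise ValueError("quartet needs a 4x4 matrix")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.isfinite(d[~np.eye(4, dtype=bool)]).all():
        raise ValueError("unresolvable quartet: non-finite distance present")
    taxa = tuple(taxa) if taxa is not None else ("a", "b", "c", "d")
    sums = []
    for (i, j), (k, l) in SPLITS:
        sums.append(d[i, j] + d[k, l])
    order = np.argsort(sums, kind="stable")  # stable = lexicographic ties
    s1, s2, s3 = (sums[o] for o in order)
    return QuartetResult(
        taxa=taxa,
        sums=(s1, s2, s3),
        split=SPLITS[order[0]],
        internal_edge=0.5 * (s2 - s1),
        violation=s3 - s2,
    )


def quartet_significance(
    q: QuartetResult, scale: float, c: float = SIGMA_REGULARIZER
) -> float:
    """Confidence of a topology call: (s2 − s1) / (violation + c·scale).

    ``scale`` should be a typical distance (e.g. the mean pairwise distance
    of the matrix) so the regulariser is dimensionally sensible.  Large when
    the internal edge is long and the four-point condition nearly holds;
    zero for a star quartet.  The raw (internal_edge, violation) pair is kept
    on the result so alternative scores can be applied post hoc.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    s2_minus_s1 = 2.0 * q.internal_edge
    return s2_minus_s1 / (q.violation + c * scale) if (q.violation + c * scale) > 0 else math.inf


def score_quartet(d: np.ndarray, taxa=None) -> QuartetResult:
    """quartet_topology plus significance (scale = mean off-diagonal)."""
    q = quartet_topology(d, taxa)
    d = np.asarray(d, dtype=float)
    scale = float(d[~np.eye(4, dtype=bool)].mean())
    return QuartetResult(
        q.taxa, q.sums, q.split, q.internal_edge, q.violation,
        sigma=quartet_significance(q, scale),
    )


def triangle_audit(d: np.ndarray, tol: float = TRIANGLE_TOL) -> list[tuple[int, int, int, float]]:
    """All ordered triples (i, j, k) with d(i,k) > d(i,j) + d(j,k), beyond a
    relative tolerance.  Returns (i, j, k, excess); an empty list means no
    violation was observed (it does not prove metricity)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    out = []
    for i, j, k in itertools.permutations(range(n), 3):
        if i < k:  # d symmetric: checking (i,j,k) covers (k,j,i)
            lhs, rhs = d[i, k], d[i, j] + d[j, k]
            if np.isfinite(rhs) and lhs > rhs + tol * max(1.0, abs(rhs)):
                out.append((i, j, k, float(lhs - rhs)))
    return out


def disagreement_table(
    d1: np.ndarray,
    d2: np.ndarray,
    labels: list[str],
    quartets=None,
) -> list[dict]:
    """Per-quartet topology calls under two metrics, worst disagreements first.

    ``quartets`` is an iterable of 4-index tuples (all combinations when
    None).  Quartets with non-finite distances under either metric are
    flagged 'unresolvable' and carry no call.  Rows are sorted by the sum of
    the two significances, descending, disagreements first.
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.shape != d2.shape:
        raise ValueError("matrices must have the same shape")
    if quartets is None:
        quartets = itertools.combinations(range(d1.shape[0]), 4)
    rows = []
    for idx in quartets:
        idx = tuple(idx)
        sub1 = d1[np.ix_(idx, idx)]
        sub2 = d2[np.ix_(idx, idx)]
        names = tuple(labels[i] for i in idx)
        row = {"taxa": names}
        try:
            q1 = score_quartet(sub1, names)
            q2 = score_quartet(sub2, names)
        except ValueError:
            row.update(status="unresolvable", agree=None, combined_sigma=0.0)
            rows.append(row)
            continue
        row.update(
            status="ok",
            topology_1=q1.newick(),
            topology_2=q2.newick(),
            sigma_1=q1.sigma,
            sigma_2=q2.sigma,
            agree=q1.split == q2.split,
            combined_sigma=q1.sigma + q2.sigma,
        )
        rows.append(row)
    rows.sort(key=lambda r: (r["agree"] is not False, -r["combined_sigma"]))
    return rows
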