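"""Independent brute-force oracles used by the test suite.

Deliberately naive: exhaustive enumeration and direct counting, sharing no
code with the implementation they check.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def brute_force_align_score(x: str, y: str, match, mismatch, gap_open, gap_extend) -> float:
    """Maximum affine-gap global alignment score by recursive enumeration of
    every alignment (no dynamic programming).  Tractable for len <= 8."""
    best = -math.inf

    def rec(i: int, j: int, last: str, acc: float) -> None:
        nonlocal best
        if i == len(x) and j == len(y):
            best = max(best, acc)
            return
        if i < len(x) and j < len(y):
            rec(i + 1, j + 1, "D", acc + (match if x[i] == y[j] else mismatch))
        if i < len(x):
            rec(i + 1, j, "U", acc + (gap_extend if last == "U" else gap_open))
        if j < len(y):
            rec(i, j + 1, "L", acc + (gap_extend if last == "L" else gap_open))

    rec(0, 0, "", 0.0)
    return best


def counting_entropy(s: str, n: int = 1) -> float:
    """Plug-in block entropy by direct word counting."""
    words = [s[i : i + n] for i in range(len(s) - n + 1)]
    total = len(words)
    h = 0.0
    for c in Counter(words).values():
        p = c / total
        h -= p * math.log2(p)
    return h


def counting_mi(pairs) -> float:
    """Plug-in MI of a list of symbol pairs by direct counting."""
    pairs = list(pairs)
    n = len(pairs)
    joint = Counter(pairs)
    left = Counter(a for a, _ in pairs)
    right = Counter(b for _, b in pairs)
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * math.log2((c / n) / ((left[a] / n) * (right[b] / n)))
    return mi


def jc_expected_p(t: float) -> float:
    """Jukes-Cantor expected p-distance at branch length t."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
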