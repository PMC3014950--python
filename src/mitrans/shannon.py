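"""Shannon (probabilistic) entropies and mutual information.

Plug-in block entropies of symbol strings and the single-letter joint
statistics of an alignment.  Per-site MI from the joint base-frequency matrix
uses exactly the same input as the log-det distance: the 4x4 (or, keeping
indels, 5x5) matrix of aligned column frequencies.

Conventions: log base 2 (bits); 0·log 0 = 0; plain plug-in estimates with no
pseudocounts.  Plug-in entropies of finite samples under-estimate, plug-in MI
over-estimates (positive bias ~ 1/N'); both are accepted as-is.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .align import GAP, PairwiseAlignment
from .kolmogorov import MIEstimate

#: memory guard for block entropies
MAX_BLOCK = 8


@dataclass(frozen=True)
class BlockDistribution:
    """Empirical distribution of n-letter words scanned along a string."""

    n: int
    counts: dict[str, int]
    total: int


@dataclass(frozen=True)
class JointFrequencyMatrix:
    """Aligned-column pair frequencies f_ab with marginals.

    ``alphabet`` is "ACGT" (indel columns dropped) or "ACGT-" (5-letter mode,
    indels retained; note indels are usually correlated along the sequence,
    so the per-site independence assumption is weaker there).
    """

    alphabet: str
    f: np.ndarray  # (k, k), sums to 1
    n_sites: int

    @property
    def fx(self) -> np.ndarray:
        return self.f.sum(axis=1)

    @property
    def fy(self) -> np.ndarray:
        return self.f.sum(axis=0)

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        if self.f.shape != (k, k):
            raise ValueError("frequency matrix shape does not match alphabet")
        if not np.isclose(self.f.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")


def block_distribution(s: str, n: int) -> BlockDistribution:
    if n < 1:
        raise ValueError("word length must be >= 1")
    if n > MAX_BLOCK:
        raise ValueError(f"word length capped at {MAX_BLOCK}")
    if n > len(s):
        raise ValueError("word length exceeds string length")
    counts = Counter(s[i : i + n] for i in range(len(s) - n + 1))
    return BlockDistribution(n, dict(counts), len(s) - n + 1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def block_entropy(s: str, n: int) -> float:
    """Plug-in entropy H_n of n-letter words, in bits per word."""
    d = block_distribution(s, n)
    p = np.array(list(d.counts.values()), dtype=float) / d.total
    return _entropy(p)


def single_letter_entropy(s: str) -> float:
    """H_1 in bits per letter; works on DNA and on 9-letter translation
    strings alike."""
    return block_entropy(s, 1)


def joint_frequencies(
    aln: PairwiseAlignment, drop_indels: bool = True
) -> JointFrequencyMatrix:
    """Column pair frequencies of an alignment.

    With ``drop_indels`` every column containing a gap is discarded first
    (4-letter mode); otherwise the gap is a fifth symbol.
    """
    alphabet = "ACGT" if drop_indels else "ACGT" + GAP
    k = len(alphabet)
    lut = np.full(256, -1, dtype=np.int64)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
    xa = lut[np.frombuffer(aln.x_aligned.encode(), dtype=np.uint8)]
    ya = lut[np.frombuffer(aln.y_aligned.encode(), dtype=np.uint8)]
    keep = (xa >= 0) & (ya >= 0)
    counts = np.bincount(xa[keep] * k + ya[keep], minlength=k * k).reshape(k, k).astype(float)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no usable (non-indel) columns in alignment")
    return JointFrequencyMatrix(alphabet, counts / n, n)


def shannon_mi(j: JointFrequencyMatrix) -> MIEstimate:
    """Plug-in mutual information of a joint frequency matrix, bits/site.

    I = sum f_ab log2( f_ab / (f_a g_b) ); always >= 0.  Total bits over the
    counted sites is ``bits * j.n_sites``.
    """
    f = j.f
    outer = np.outer(j.fx, j.fy)
    mask = f > 0
    i = float((f[mask] * np.log2(f[mask] / outer[mask])).sum())
    return MIEstimate(bits=max(0.0, i), method="shannon", codec=None)


def marginal_entropies(j: JointFrequencyMatrix) -> tuple[float, float]:
    """Single-letter entropies (bits/site) of the two alignment rows, from
    the joint matrix marginals — the same input the log-det distance uses."""
    return _entropy(j.fx), _entropy(j.fy)
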