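"""Pairwise distance measures derived from mutual information and from
substitution counts.

MI-normalised distances (NCD/NSD saturate at 1 for unrelated pairs; their
log-transformed versions are approximately additive when MI decays
exponentially with evolutionary time but are not guaranteed to satisfy the
triangle inequality), the paralinear/log-det distance (additive under general
stationary Markov substitution with site-homogeneous rates), the p and
Poisson-corrected p distances, and two Kimura-two-parameter-model distances.

Natural log is used for log-det and the Kimura distances (substitutions/site
convention); base-2 log for MI-derived quantities (bits).  Topology calls are
scale-invariant per metric, so the unit mixing is harmless downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import PairwiseAlignment, ScoringScheme, global_align
from .kolmogorov import DEFAULT_CODEC, MIEstimate, csize, mi_align, mi_concat
from .seqio import NucleotideSequence, length_filter
from .shannon import (
    JointFrequencyMatrix,
    joint_frequencies,
    marginal_entropies,
    shannon_mi,
)

METRICS = (
    "ncd", "nsd", "logmi", "logdet", "p", "pcp", "kimura1", "kimura2",
)

#: default clamp ceiling for NCD (codec noise can push it slightly above 1)
NCD_CEILING = 1.1


@dataclass(frozen=True)
class DistanceResult:
    metric: str
    value: float  # >= 0 or +inf
    finite: bool = True
    note: str = ""
    meta: dict = field(default_factory=dict)


def _result(metric: str, value: float, note: str = "", **meta) -> DistanceResult:
    return DistanceResult(metric, value, math.isfinite(value), note, dict(meta))


@dataclass(frozen=True)
class KimuraFractions:
    """Transition (P) and transversion (Q) fractions of non-indel sites."""

    P: float
    Q: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("invalid substitution fractions")


def ncd(i: MIEstimate, cx, cy) -> DistanceResult:
    """Normalized compression distance 1 − I / max(C(x), C(y)), clamped to
    [0, 1.1]; clamping is recorded in the result note."""
    bx = cx.bits if hasattr(cx, "bits") else float(cx)
    by = cy.bits if hasattr(cy, "bits") else float(cy)
    if bx <= 0 or by <= 0:
        raise ValueError("zero complexity in NCD denominator")
    raw = 1.0 - i.bits / max(bx, by)
    val = min(max(raw, 0.0), NCD_CEILING)
    note = "" if val == raw else f"clamped from {raw:.6g}"
    return _result("ncd", val, note, codec=i.codec)


def nsd(i_bits: float, hx: float, hy: float) -> DistanceResult:
    """Normalized Shannon distance 1 − I / max(H(x), H(y))."""
    if hx <= 0 or hy <= 0:
        raise ValueError("zero entropy (constant sequence) in NSD denominator")
    return _result("nsd", 1.0 - i_bits / max(hx, hy))


def log_mi(i_bits: float, hx: float, hy: float, metric: str = "logmi") -> DistanceResult:
    """log-MI distance −log2( I / max(H(x), H(y)) ); +inf when I <= 0.

    Applies unchanged to compression-based estimates (pass C(x), C(y) as the
    normalisers) and to Shannon estimates.
    """
    if hx <= 0 or hy <= 0:
        raise ValueError("zero normaliser in log-MI")
    if i_bits <= 0:
        return _result(metric, math.inf, "non-positive MI")
    return _result(metric, -math.log2(i_bits / max(hx, hy)))


def log_det(j: JointFrequencyMatrix) -> DistanceResult:
    """Paralinear / log-det distance
    −(1/4)·ln[ det F / sqrt(det Dx · det Dy) ] on the 4-letter joint matrix;
    +inf when det F <= 0 (saturated or meaningless pair)."""
    if j.alphabet != "ACGT":
        raise ValueError("log-det requires the 4-letter (indel-free) matrix")
    fx, fy = j.fx, j.fy
    if (fx <= 0).any() or (fy <= 0).any():
        raise ValueError("degenerate composition: zero marginal frequency")
    det = float(np.linalg.det(j.f))
    if det <= 0:
        return _result("logdet", math.inf, "non-positive determinant")
    norm = math.sqrt(float(np.prod(fx)) * float(np.prod(fy)))
    return _result("logdet", -0.25 * math.log(det / norm))


def p_distance(j: JointFrequencyMatrix) -> DistanceResult:
    """Fraction of non-indel sites at which the two sequences disagree."""
    if j.alphabet != "ACGT":
        raise ValueError("p-distance requires the 4-letter matrix")
    p = 1.0 - float(np.trace(j.f))
    return _result("p", p, n_sites=j.n_sites)


def pc_p_distance(j: JointFrequencyMatrix) -> DistanceResult:
    """Poisson-corrected p-distance −ln(1 − p); +inf at p >= 1."""
    p = p_distance(j).value
    if p >= 1.0:
        return _result("pcp", math.inf, "saturated")
    return _result("pcp", -math.log(1.0 - p))


_TI = ((0, 2), (2, 0), (1, 3), (3, 1))  # A<->G, C<->T in ACGT indexing


def kimura_fractions(j: JointFrequencyMatrix) -> KimuraFractions:
    if j.alphabet != "ACGT":
        raise ValueError("Kimura fractions require the 4-letter matrix")
    p = float(sum(j.f[a, b] for a, b in _TI))
    q = float(1.0 - np.trace(j.f) - p)
    return KimuraFractions(p, max(q, 0.0), j.n_sites)


def kimura1(kf: KimuraFractions) -> DistanceResult:
    """Kimura two-parameter estimate of total substitutions per site,
    −(1/2)·ln[(1 − 2P − Q)·sqrt(1 − 2Q)]; +inf outside the formula domain."""
    a = 1.0 - 2.0 * kf.P - kf.Q
    b = 1.0 - 2.0 * kf.Q
    if a <= 0 or b <= 0:
        return _result("kimura1", math.inf, "outside model domain")
    return _result("kimura1", -0.5 * math.log(a * math.sqrt(b)))


def kimura2(j: JointFrequencyMatrix) -> DistanceResult:
    """Coarse-grained log-MI distance under the Kimura lumping (reconstructed).

    The Kimura-model log-likelihood is essentially a coarse-grained MI in
    which substitutions are lumped into three classes.  Here the 4x4 joint is
    collapsed to {identical, transition, transversion}, the same lumping is
    applied to the independence surrogate f_a·g_b, and the log-MI form is
    taken on the resulting divergence.  The exact published form of this
    variant is not available; this reconstruction preserves its two stated
    ingredients (Kimura lumping, MI form).
    """
    if j.alphabet != "ACGT":
        raise ValueError("kimura2 requires the 4-letter matrix")
    ident = float(np.trace(j.f))
    ti = float(sum(j.f[a, b] for a, b in _TI))
    tv = max(1.0 - ident - ti, 0.0)
    outer = np.outer(j.fx, j.fy)
    q_ident = float(np.trace(outer))
    q_ti = float(sum(outer[a, b] for a, b in _TI))
    q_tv = max(1.0 - q_ident - q_ti, 0.0)
    i_cg = 0.0
    for fc, qc in ((ident, q_ident), (ti, q_ti), (tv, q_tv)):
        if fc > 0 and qc > 0:
            i_cg += fc * math.log2(fc / qc)
    hx, hy = marginal_entropies(j)
    if i_cg <= 0:
        return _result("kimura2", math.inf, "non-positive coarse-grained MI")
    return log_mi(i_cg, hx, hy, metric="kimura2")


def pair_distance(
    x: NucleotideSequence,
    y: NucleotideSequence,
    metric: str,
    aln: PairwiseAlignment | None = None,
    estimator: str = "shannon",
    codec: str = DEFAULT_CODEC,
    scoring: ScoringScheme | None = None,
    band: int | None = None,
    conditional: bool = True,
) -> DistanceResult:
    """Distance between one pair of sequences under a named metric.

    ``estimator`` selects the MI source for ncd/nsd/logmi: "shannon" (joint
    column frequencies), "align" (translation-string compression) or "concat"
    (concatenation compression).  Count-based metrics always use the
    alignment's joint frequencies.  If ``aln`` is omitted a global alignment
    is computed first.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "ncd" and estimator == "shannon":
        estimator = "align"  # NCD is compression-based by definition
    if aln is None:
        aln = global_align(x, y, scoring=scoring, band=band)

    if metric in ("logdet", "p", "pcp", "kimura1", "kimura2") or (
        metric in ("nsd", "logmi") and estimator == "shannon"
    ):
        j = joint_frequencies(aln, drop_indels=True)
        if metric == "logdet":
            return log_det(j)
        if metric == "p":
            return p_distance(j)
        if metric == "pcp":
            return pc_p_distance(j)
        if metric == "kimura1":
            return kimura1(kimura_fractions(j))
        if metric == "kimura2":
            return kimura2(j)
        i = shannon_mi(j).bits
        hx, hy = marginal_entropies(j)
        return nsd(i, hx, hy) if metric == "nsd" else log_mi(i, hx, hy)

    # compression-based estimators
    if estimator == "align":
        est = mi_align(x, y, aln, codec=codec, conditional=conditional)
    elif estimator == "concat":
        est = mi_concat(x, y, codec=codec)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    cx = csize(x.letters.encode(), codec)
    cy = csize(y.letters.encode(), codec)
    if metric == "ncd":
        return ncd(est, cx, cy)
    if metric == "nsd":
        r = nsd(est.bits, cx.bits, cy.bits)
        return _result("nsd", r.value, codec=codec, estimator=estimator)
    return log_mi(est.bits, cx.bits, cy.bits)


def distance_matrix(
    seqs: list[NucleotideSequence],
    metric: str,
    length_ratio: float = 0.75,
    alignments: dict[tuple[int, int], PairwiseAlignment] | None = None,
    **kwargs,
) -> tuple[np.ndarray, list[str], dict[tuple[int, int], str]]:
    """Symmetric all-pairs distance matrix with a zero diagonal.

    Pairs failing the length filter get NaN and an entry in the returned
    notes dict rather than being silently dropped.  Precomputed alignments
    may be supplied keyed by the (i, j) index pair, i < j.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    d = np.zeros((n, n))
    notes: dict[tuple[int, int], str] = {}
    for i in range(n):
        for jj in range(i + 1, n):
            if not length_filter(seqs[i], seqs[jj], length_ratio):
                d[i, jj] = d[jj, i] = np.nan
                notes[(i, jj)] = "length-filtered"
                continue
            aln = alignments.get((i, jj)) if alignments else None
            res = pair_distance(seqs[i], seqs[jj], metric, aln=aln, **kwargs)
            d[i, jj] = d[jj, i] = res.value
            if res.note:
                notes[(i, jj)] = res.note
    return d, [s.id for s in seqs], notes


def write_phylip(d: np.ndarray, labels: list[str], path, lower: bool = False) -> None:
    """PHYLIP distance-matrix format (square by default, lower-triangle
    optional).  Infinite entries are written as -1.0 per common convention
    of downstream tools that treat negatives as missing."""
    n = len(labels)
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, lab in enumerate(labels):
            cols = range(i) if lower else range(n)
            vals = []
            for j in cols:
                v = d[i, j]
                vals.append(f"{-1.0 if not np.isfinite(v) else v:.6f}")
            fh.write(f"{lab[:10]:<10s}  " + "  ".join(vals) + "\n")


def read_phylip(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return np.array(rows), labels
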