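"""Synthetic sequence evolution with known ground truth.

Continuous-time Markov substitution models (JC69, K2P, HKY85) with the rate
matrix scaled so that one unit of branch length equals one expected
substitution per site; per-site transition probabilities come from the
matrix exponential exp(Q·t).  Optional indels are applied after substitution
on each branch as Poisson events with geometric lengths.  Chains and
quartets evolve each branch independently (Markov property), so true model
distances are additive on the generating tree by construction.

Also provides the triangle-inequality counter-example: encode each DNA
letter as two bits (purine/pyrimidine and weak/strong pairing), then
re-randomise one bit per site.  The two derived sequences share one bit of
information per site with the original and none with each other, which sends
the log-MI distance between them to infinity while the two finite legs stay
at one — a constructed violation of the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .seqio import NucleotideSequence

LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {c: i for i, c in enumerate("ACGT")}

MODELS = ("JC", "K2P", "HKY")

#: default transition/transversion rate ratio for K2P/HKY
DEFAULT_KAPPA = 2.0


@dataclass(frozen=True)
class EvolutionParams:
    model: str = "JC"
    branch_length: float = 0.1  # expected substitutions per site
    kappa: float = DEFAULT_KAPPA
    base_freqs: tuple[float, float, float, float] | None = None  # HKY only
    indel_rate: float = 0.0  # expected events per site
    indel_mean_len: float = 3.0  # geometric mean length
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.branch_length < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.base_freqs is not None:
            f = np.asarray(self.base_freqs, float)
            if f.shape != (4,) or (f <= 0).any() or not np.isclose(f.sum(), 1.0):
                raise ValueError("base_freqs must be 4 positive values summing to 1")


@dataclass(frozen=True)
class QuartetSpec:
    """Four-taxon tree ((a,b),(c,d)) with terminal edges ta..td and one
    internal edge, plus the substitution parameters and root length."""

    lengths: tuple[float, float, float, float]  # terminal edges a,b,c,d
    internal: float
    params: EvolutionParams = field(default_factory=EvolutionParams)
    root_length: int = 5000

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.lengths) or self.internal < 0:
            raise ValueError("edge lengths must be non-negative")

    def additive_matrix(self) -> np.ndarray:
        """True model distances between the four leaves."""
        ta, tb, tc, td = self.lengths
        e = self.internal
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = ta + tb
        d[0, 2] = d[2, 0] = ta + e + tc
        d[0, 3] = d[3, 0] = ta + e + td
        d[1, 2] = d[2, 1] = tb + e + tc
        d[1, 3] = d[3, 1] = tb + e + td
        d[2, 3] = d[3, 2] = tc + td
        return d


def rate_matrix(model: str, kappa: float = DEFAULT_KAPPA,
                base_freqs=None) -> np.ndarray:
    """Normalised rate matrix Q (rows sum to 0, expected rate 1/site/unit).

    Letter order A, C, G, T; transitions are A<->G and C<->T.
    """
    pi = np.full(4, 0.25) if base_freqs is None else np.asarray(base_freqs, float)
    if model == "JC":
        r = np.ones((4, 4))
    elif model in ("K2P", "HKY"):
        r = np.ones((4, 4))
        r[_IDX["A"], _IDX["G"]] = r[_IDX["G"], _IDX["A"]] = kappa
        r[_IDX["C"], _IDX["T"]] = r[_IDX["T"], _IDX["C"]] = kappa
    else:
        raise ValueError(f"unknown model {model!r}")
    q = r * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = float(-(pi * np.diag(q)).sum())
    return q / mu


def stationary_freqs(p: EvolutionParams) -> np.ndarray:
    if p.model == "HKY" and p.base_freqs is not None:
        return np.asarray(p.base_freqs, float)
    return np.full(4, 0.25)


def _to_ints(letters: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int64)
    for c, i in _IDX.items():
        lut[ord(c)] = i
    out = lut[np.frombuffer(letters.encode(), dtype=np.uint8)]
    if (out < 0).any():
        raise ValueError("sequence contains non-ACGT letters")
    return out


def _to_str(ints: np.ndarray) -> str:
    return LETTERS[ints].tobytes().decode("ascii")


def random_sequence(length: int, p: EvolutionParams | None = None,
                    rng: np.random.Generator | None = None,
                    seq_id: str = "root") -> NucleotideSequence:
    """Draw an i.i.d. sequence from the model's stationary distribution."""
    p = p or EvolutionParams()
    rng = rng or np.random.default_rng(p.seed)
    ints = rng.choice(4, size=length, p=stationary_freqs(p))
    return NucleotideSequence(seq_id, _to_str(ints))


def _substitute(ints: np.ndarray, p: EvolutionParams, t: float,
                rng: np.random.Generator) -> np.ndarray:
    if t == 0:
        return ints.copy()
    q = rate_matrix(p.model, p.kappa, p.base_freqs)
    pmat = expm(q * t)
    cum = np.cumsum(pmat, axis=1)
    u = rng.random(ints.size)
    return (u[:, None] > cum[ints]).sum(axis=1)


def _apply_indels(ints: np.ndarray, p: EvolutionParams,
                  rng: np.random.Generator) -> np.ndarray:
    if p.indel_rate == 0:
        return ints
    n_events = rng.poisson(p.indel_rate * ints.size)
    pi = stationary_freqs(p)
    for _ in range(n_events):
        length = rng.geometric(1.0 / p.indel_mean_len)
        if ints.size == 0:
            break
        pos = int(rng.integers(0, ints.size + 1))
        if rng.random() < 0.5:  # insertion
            ins = rng.choice(4, size=length, p=pi)
            ints = np.concatenate([ints[:pos], ins, ints[pos:]])
        else:  # deletion
            ints = np.concatenate([ints[:pos], ints[pos + length:]])
    return ints


def evolve(seq: NucleotideSequence, p: EvolutionParams,
           rng: np.random.Generator | None = None,
           seq_id: str | None = None) -> NucleotideSequence:
    """Evolve a sequence along one branch: i.i.d. substitution via exp(Q t),
    then indels.  Deterministic given the generator state / seed."""
    rng = rng or np.random.default_rng(p.seed)
    ints = _substitute(_to_ints(seq.letters), p, p.branch_length, rng)
    ints = _apply_indels(ints, p, rng)
    return NucleotideSequence(seq_id or f"{seq.id}+{p.branch_length:g}", _to_str(ints))


def simulate_pair(length: int, p: EvolutionParams,
                  seed: int | None = None) -> tuple[NucleotideSequence, NucleotideSequence]:
    """An ancestor x (stationary) and a descendant y at the given branch
    length; the pair's true model distance is p.branch_length."""
    rng = np.random.default_rng(p.seed if seed is None else seed)
    x = random_sequence(length, p, rng, "x")
    y = evolve(x, p, rng, "y")
    return x, y


def simulate_chain(length: int, branch_lengths, p: EvolutionParams,
                   seed: int | None = None) -> list[NucleotideSequence]:
    """Markov chain x0 -> x1 -> ... with independent evolution per branch."""
    rng = np.random.default_rng(p.seed if seed is None else seed)
    seqs = [random_sequence(length, p, rng, "x0")]
    for k, t in enumerate(branch_lengths, start=1):
        pk = replace(p, branch_length=float(t))
        seqs.append(evolve(seqs[-1], pk, rng, f"x{k}"))
    return seqs


def simulate_quartet(spec: QuartetSpec,
                     seed: int | None = None) -> list[NucleotideSequence]:
    """Four leaf sequences a,b,c,d from the tree ((a,b),(c,d))."""
    p = spec.params
    rng = np.random.default_rng(p.seed if seed is None else seed)
    root = random_sequence(spec.root_length, p, rng, "root")
    ta, tb, tc, td = spec.lengths
    a = evolve(root, replace(p, branch_length=ta), rng, "a")
    b = evolve(root, replace(p, branch_length=tb), rng, "b")
    mid = evolve(root, replace(p, branch_length=spec.internal), rng, "mid")
    c = evolve(mid, replace(p, branch_length=tc), rng, "c")
    d = evolve(mid, replace(p, branch_length=td), rng, "d")
    return [a, b, c, d]


# counter-example bit encoding: bit1 = purine(0)/pyrimidine(1),
# bit2 = weak A/T (0) / strong C/G (1); (b1,b2) -> letter
_BITS_TO_LETTER = np.array(
    [_IDX["A"], _IDX["G"], _IDX["T"], _IDX["C"]], dtype=np.int64
)  # (0,0)=A (0,1)=G (1,0)=T (1,1)=C


def counterexample_triple(
    length: int, seed: int | None = None
) -> tuple[NucleotideSequence, NucleotideSequence, NucleotideSequence]:
    """The constructed triple (x, y, z) violating the triangle inequality
    for log-MI distances.

    x is i.i.d. uniform; y re-randomises the purine/pyrimidine bit of every
    site but keeps the weak/strong bit; z does the opposite.  Hence
    I(x:y) = I(x:z) = 1 bit/site while I(y:z) = 0.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    b1 = rng.integers(0, 2, length)
    b2 = rng.integers(0, 2, length)
    x = _BITS_TO_LETTER[2 * b1 + b2]
    y = _BITS_TO_LETTER[2 * rng.integers(0, 2, length) + b2]
    z = _BITS_TO_LETTER[2 * b1 + rng.integers(0, 2, length)]
    return (
        NucleotideSequence("x", _to_str(x)),
        NucleotideSequence("y", _to_str(y)),
        NucleotideSequence("z", _to_str(z)),
    )
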