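"""Compression-based (algorithmic) complexity and mutual information.

The compressed size of a byte string is an upper bound on its Kolmogorov
complexity; differences of compressed sizes estimate conditional complexity
and mutual information.  Two estimators are provided:

* ``mi_align`` — alignment-based: I(x:y) ≈ C(x) − C(t(x->y) | x), where the
  translation string t holds exactly what is needed to rebuild y from x.
  Conditional compression is realised as a concatenation difference
  C(x ∥ SEP ∥ t) − C(x) (general-purpose codecs have no native conditioning
  interface); the unconditional variant uses C(t) directly.
* ``mi_concat`` — alignment-free: I(x:y) ≈ C(x) + C(y) − C(x ∥ y).

Both are symmetrised by averaging the two directions/orders; directional
values are retained because their asymmetry is itself informative.  Estimates
can be negative for unalignable pairs and are reported as-is, not clamped.
Imperfect codecs very likely under- rather than over-estimate MI; no
correction is applied.
"""

from __future__ import annotations

import bz2
import lzma
import zlib
from dataclasses import dataclass
from typing import Callable

from .align import PairwiseAlignment
from .seqio import NucleotideSequence
from .transcode import encode

#: separator byte outside both the DNA and the nine-letter alphabets
SEP = b"|"

CODECS: dict[str, Callable[[bytes], bytes]] = {
    "deflate": lambda b: zlib.compress(b, 9),
    "bzip2": lambda b: bz2.compress(b, 9),
    "lzma": lzma.compress,
}

DEFAULT_CODEC = "lzma"


@dataclass(frozen=True)
class CompressedSize:
    """Compressed length in bits (8 x compressed byte count)."""

    bits: int
    codec: str
    payload_kind: str = "raw-sequence"

    def __post_init__(self) -> None:
        if self.bits < 0:
            raise ValueError("compressed size cannot be negative")


@dataclass(frozen=True)
class MIEstimate:
    """A mutual-information value in bits, with provenance.

    ``bits`` is the symmetric estimate (mean of the two directional values
    where applicable); the directional values are kept alongside.
    """

    bits: float
    method: str  # "align" | "concat" | "shannon"
    direction: str = "symmetric"
    codec: str | None = None
    forward_bits: float | None = None
    reverse_bits: float | None = None


def _compressor(codec: str) -> Callable[[bytes], bytes]:
    try:
        return CODECS[codec]
    except KeyError:
        raise ValueError(
            f"unknown codec {codec!r}; registered: {sorted(CODECS)}"
        ) from None


def csize(payload: bytes, codec: str = DEFAULT_CODEC,
          payload_kind: str = "raw-sequence") -> CompressedSize:
    """Compressed size of a byte payload, in bits."""
    if not payload:
        raise ValueError("cannot size an empty payload")
    comp = _compressor(codec)
    return CompressedSize(8 * len(comp(payload)), codec, payload_kind)


def cond_csize(t: bytes, x: bytes, codec: str = DEFAULT_CODEC) -> CompressedSize:
    """Conditional compressed size C(t | x) ≈ C(x ∥ SEP ∥ t) − C(x), floored
    at zero.  With an empty context this degenerates to C(t)."""
    if not t:
        raise ValueError("cannot size an empty payload")
    comp = _compressor(codec)
    if not x:
        return CompressedSize(8 * len(comp(t)), codec, "translation-string")
    joint = 8 * len(comp(x + SEP + t))
    alone = 8 * len(comp(x))
    return CompressedSize(max(0, joint - alone), codec, "translation-string")


def _seq_bytes(s: NucleotideSequence) -> bytes:
    return s.letters.encode("ascii")


def mi_align(
    x: NucleotideSequence,
    y: NucleotideSequence,
    aln: PairwiseAlignment,
    codec: str = DEFAULT_CODEC,
    conditional: bool = True,
) -> MIEstimate:
    """Alignment-based MI estimate in bits (symmetrised over directions).

    Directional value for x->y is C(x) − C(t(x->y) | x) when ``conditional``,
    else C(x) − C(t(x->y)).  May be negative for pairs whose alignment is
    meaningless.
    """
    if aln.x_degapped != x.letters or aln.y_degapped != y.letters:
        raise ValueError("alignment does not degap to the supplied sequences")
    bx, by = _seq_bytes(x), _seq_bytes(y)
    t_xy = bytes(encode(aln, "xy"))
    t_yx = bytes(encode(aln, "yx"))
    cx = csize(bx, codec).bits
    cy = csize(by, codec).bits
    if conditional:
        ct_xy = cond_csize(t_xy, bx, codec).bits
        ct_yx = cond_csize(t_yx, by, codec).bits
    else:
        ct_xy = csize(t_xy, codec, "translation-string").bits
        ct_yx = csize(t_yx, codec, "translation-string").bits
    fwd = cx - ct_xy
    rev = cy - ct_yx
    return MIEstimate(
        bits=0.5 * (fwd + rev), method="align", codec=codec,
        forward_bits=float(fwd), reverse_bits=float(rev),
    )


def mi_concat(
    x: NucleotideSequence, y: NucleotideSequence, codec: str = DEFAULT_CODEC
) -> MIEstimate:
    """Alignment-free MI estimate C(x) + C(y) − C(x ∥ y), averaged over both
    concatenation orders."""
    bx, by = _seq_bytes(x), _seq_bytes(y)
    cx = csize(bx, codec).bits
    cy = csize(by, codec).bits
    fwd = cx + cy - csize(bx + by, codec, "concatenation").bits
    rev = cx + cy - csize(by + bx, codec, "concatenation").bits
    return MIEstimate(
        bits=0.5 * (fwd + rev), method="concat", codec=codec,
        forward_bits=float(fwd), reverse_bits=float(rev),
    )
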