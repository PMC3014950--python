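"""Translation strings: a lossless, directional re-encoding of an alignment.

Each column of a pairwise global alignment of x and y maps to one symbol of a
nine-letter alphabet, chosen so that the resulting string t(x->y) holds
exactly the information needed to rebuild y when x is known — and no more:

====================  ======  =======================================
column (x̂_i, ŷ_i)     symbol  meaning
====================  ======  =======================================
identical letters      '0'    copy the current letter of x
('-', b)               b      insertion: emit b, consume nothing
(a, '-')               '-'    deletion: consume a, emit nothing
A<->G or C<->T         '1'    transition (purine<->purine etc.)
A<->C or T<->G         '2'    transversion, class 1
A<->T or G<->C         '3'    transversion, class 2
====================  ======  =======================================

Substitution symbols are *relative*: '1' applied to A yields G and applied to
G yields A, so the same code works in both directions.  Gap columns are what
makes t(x->y) != t(y->x): an insertion into y must spell the new letter, a
deletion needs only a marker.  Compressing t therefore upper-bounds the
conditional Kolmogorov complexity C(y|x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import GAP, PairwiseAlignment
from .seqio import NucleotideSequence

MATCH = "0"
DEL = "-"
TRANSITION = "1"
TRANSV_1 = "2"
TRANSV_2 = "3"
INSERTIONS = "ACGT"  # insertion symbol == inserted letter

ALPHABET9 = "0ACGT-123"

# partner letter under each substitution class
_PARTNER = {
    TRANSITION: {"A": "G", "G": "A", "C": "T", "T": "C"},
    TRANSV_1: {"A": "C", "C": "A", "T": "G", "G": "T"},
    TRANSV_2: {"A": "T", "T": "A", "G": "C", "C": "G"},
}

_SUB_CLASS = {}
for _sym, _map in _PARTNER.items():
    for _a, _b in _map.items():
        _SUB_CLASS[(_a, _b)] = _sym


@dataclass(frozen=True)
class TranslationString:
    """Nine-letter string t(source->target) of the same length as the
    alignment it was derived from."""

    symbols: str
    source_id: str
    target_id: str

    def __len__(self) -> int:
        return len(self.symbols)

    def __bytes__(self) -> bytes:
        return self.symbols.encode("ascii")


def classify_column(a: str, b: str) -> str:
    """Map one aligned column (a from x̂, b from ŷ) to its symbol."""
    if a == GAP and b == GAP:
        raise ValueError("all-gap column is not a valid alignment column")
    if a == b:
        return MATCH
    if a == GAP:
        if b not in INSERTIONS:
            raise ValueError(f"invalid inserted letter {b!r}")
        return b
    if b == GAP:
        return DEL
    try:
        return _SUB_CLASS[(a, b)]
    except KeyError:
        raise ValueError(f"invalid column ({a!r}, {b!r})") from None


# vectorised encoder: letters A,C,G,T,- -> 0..4; pair code 5*a+b -> symbol
_L2I = {c: i for i, c in enumerate("ACGT-")}
_PAIR_LUT = np.zeros(25, dtype="U1")
for _a, _ia in _L2I.items():
    for _b, _ib in _L2I.items():
        if _a == GAP and _b == GAP:
            _PAIR_LUT[5 * _ia + _ib] = "?"
        else:
            _PAIR_LUT[5 * _ia + _ib] = classify_column(_a, _b)


def encode(aln: PairwiseAlignment, direction: str = "xy") -> TranslationString:
    """Translation string of an alignment; ``direction`` "xy" yields
    t(x->y) (recover y from x), "yx" the reverse."""
    if direction == "xy":
        src, tgt = aln.x_aligned, aln.y_aligned
        sid, tid = aln.x_id, aln.y_id
    elif direction == "yx":
        src, tgt = aln.y_aligned, aln.x_aligned
        sid, tid = aln.y_id, aln.x_id
    else:
        raise ValueError("direction must be 'xy' or 'yx'")
    ai = np.fromiter((_L2I[c] for c in src), dtype=np.int8, count=len(src))
    bi = np.fromiter((_L2I[c] for c in tgt), dtype=np.int8, count=len(tgt))
    syms = _PAIR_LUT[5 * ai.astype(np.intp) + bi]
    return TranslationString("".join(syms), sid, tid)


def decode(x: NucleotideSequence, t: TranslationString) -> NucleotideSequence:
    """Rebuild the target sequence from the source x and t(x->target).

    Walks t consuming letters of x: '0' copies, substitution codes emit the
    partner letter of the consumed letter, insertions emit their own letter
    without consuming, '-' consumes silently.
    """
    sym = np.frombuffer(bytes(t), dtype=np.uint8)
    ins_bytes = np.frombuffer(INSERTIONS.encode(), dtype=np.uint8)
    is_ins = np.isin(sym, ins_bytes)
    consumes = ~is_ins
    n_consumed = int(consumes.sum())
    if n_consumed != len(x.letters):
        raise ValueError(
            "translation/sequence length mismatch: "
            f"t consumes {n_consumed} letters, x has {len(x.letters)}"
        )
    xb = np.frombuffer(x.letters.encode(), dtype=np.uint8)
    # letter of x consumed at each consuming position of t
    src_at = np.zeros(sym.size, dtype=np.uint8)
    src_at[consumes] = xb
    out = np.zeros(sym.size, dtype=np.uint8)
    m_match = sym == ord(MATCH)
    out[m_match] = src_at[m_match]
    for code, pmap in _PARTNER.items():
        mask = sym == ord(code)
        if mask.any():
            lut = np.zeros(256, dtype=np.uint8)
            for a, b in pmap.items():
                lut[ord(a)] = ord(b)
            partners = lut[src_at[mask]]
            if (partners == 0).any():
                raise ValueError("substitution code applied to invalid letter")
            out[mask] = partners
    out[is_ins] = sym[is_ins]
    return NucleotideSequence(t.target_id, out[out != 0].tobytes().decode("ascii"))


def save_translation(t: TranslationString, path) -> None:
    """Single-record FASTA-like text; header carries the direction."""
    with open(path, "w") as fh:
        fh.write(f">{t.source_id}->{t.target_id}\n")
        for k in range(0, len(t.symbols), 70):
            fh.write(t.symbols[k : k + 70] + "\n")


def load_translation(path) -> TranslationString:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(">") or "->" not in header:
            raise ValueError("not a translation-string file")
        src, tgt = header[1:].split("->", 1)
        body = "".join(line.strip() for line in fh)
    if set(body) - set(ALPHABET9):
        raise ValueError("invalid symbols in translation string")
    return TranslationString(body, src, tgt)
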