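"""Sequence input/output and hygiene.

Reads and writes multi-record FASTA (via Biopython), removes IUPAC wildcard
characters, rejects sequences whose wildcard content marks them as incomplete,
and handles circular genomes (mitochondrial DNA forms a closed ring, so two
records of the same molecule may start at arbitrary rotations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

#: IUPAC nucleotide ambiguity codes (anything that is not a concrete base).
WILDCARDS = frozenset("NRYSWKMBDHVU")

#: Default tolerated wildcard fraction before a record is called incomplete.
DEFAULT_MAX_WILDCARD_FRAC = 0.01


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over {A,C,G,T} (wildcards only before cleaning)."""

    id: str
    letters: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.letters)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")


def read_fasta(path, circular: bool = False) -> list[NucleotideSequence]:
    """Read all records of a FASTA file, preserving order, upper-casing letters.

    Raises ``ValueError`` on an empty file or on duplicate record ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        out.append(NucleotideSequence(rec.id, str(rec.seq).upper(), circular=circular))
    return out


def write_fasta(seqs, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.letters), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def clean(
    seq: NucleotideSequence,
    max_wildcard_frac: float = DEFAULT_MAX_WILDCARD_FRAC,
) -> NucleotideSequence:
    """Delete wildcard letters; reject incomplete sequences.

    A record whose wildcard fraction exceeds ``max_wildcard_frac`` is treated
    as an incomplete sequence and rejected, mirroring the usual hygiene step
    for public mtDNA downloads.  Deletion (rather than imputation) is
    conservative for downstream information estimates.
    """
    if not 0.0 <= max_wildcard_frac <= 1.0:
        raise ValueError("max_wildcard_frac must be in [0, 1]")
    letters = seq.letters.upper()
    bad = [c for c in letters if c not in ALPHABET]
    unknown = [c for c in bad if c not in WILDCARDS]
    if unknown:
        raise ValueError(
            f"{seq.id}: non-nucleotide characters {sorted(set(unknown))!r}"
        )
    frac = len(bad) / len(letters) if letters else 1.0
    if frac > max_wildcard_frac:
        raise ValueError(
            f"{seq.id}: incomplete sequence "
            f"({frac:.1%} wildcards > {max_wildcard_frac:.1%} allowed)"
        )
    kept = "".join(c for c in letters if c in ALPHABET)
    if not kept:
        raise ValueError(f"{seq.id}: empty after wildcard cleaning")
    return replace(seq, letters=kept)


def rotate(seq: NucleotideSequence, offset: int) -> NucleotideSequence:
    """Cyclic shift of a circular sequence by ``offset`` positions."""
    if not seq.circular:
        raise ValueError(f"{seq.id}: cannot rotate a non-circular sequence")
    n = len(seq.letters)
    k = offset % n
    return replace(seq, letters=seq.letters[k:] + seq.letters[:k])


def auto_rotate_offset(
    seq: NucleotideSequence, partner: NucleotideSequence, k: int = 20
) -> int:
    """Heuristic rotation offset: first exact k-mer of ``partner`` found in
    the doubled ``seq``.  Returns 0 when no seed matches.

    Optional helper; the rotation criterion for real circular genomes is a
    judgement call and callers may supply their own offset.
    """
    if len(partner.letters) < k or len(seq.letters) < k:
        return 0
    doubled = seq.letters + seq.letters
    for start in range(0, min(len(partner.letters) - k + 1, 200)):
        seed = partner.letters[start : start + k]
        pos = doubled.find(seed)
        if pos >= 0:
            return (pos - start) % len(seq.letters)
    return 0


def length_filter(
    a: NucleotideSequence, b: NucleotideSequence, ratio: float = 0.75
) -> bool:
    """True iff min(|a|,|b|) >= ratio * max(|a|,|b|).

    Guards against pairs whose length difference forces so many indels that a
    global alignment stops being meaningful.
    """
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    la, lb = len(a.letters), len(b.letters)
    return min(la, lb) >= ratio * max(la, lb)
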