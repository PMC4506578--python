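"""Minimal nucleotide utilities shared across the package.

The codon table is spelled out explicitly (rather than delegating to an
external translator) because translation of CDR3 junctions is a contract of
this package and is cross-checked against an independent oracle in the tests.
"""

from __future__ import annotations

from .errors import FrameError

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

#: Standard genetic code, codon -> one-letter amino acid ('*' = stop).
CODON_TABLE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(nt: str) -> str:
    """Reverse complement of a plus-strand nucleotide string."""
    return nt.translate(_COMPLEMENT)[::-1]


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string; stops render as ``*``.

    Raises
    ------
    FrameError
        If the length is not divisible by three.
    """
    if len(nt) % 3 != 0:
        raise FrameError(f"length {len(nt)} not divisible by 3")
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))


def is_valid_nt(nt: str, allow_n: bool = False) -> bool:
    alphabet = set("ACGTN" if allow_n else "ACGT")
    return len(nt) > 0 and set(nt) <= alphabet
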