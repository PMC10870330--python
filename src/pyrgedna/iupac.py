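"""IUPAC nucleotide set algebra.

Every IUPAC symbol denotes a nonempty subset of {A, C, G, T}; a degenerate
oligo therefore denotes a pool of concrete oligos whose size is the product
of the per-position set cardinalities (its *fold-degeneracy*).  This module
provides the expansion, complementation, degeneracy and degenerate-aware
mismatch arithmetic that the primer, control, read-processing and curation
modules build on.

Mismatch semantics: a template (window) base mismatches a primer position
iff it is not a member of that position's IUPAC set.  This equals the
minimum Hamming distance between the window and any concrete expansion of
the primer.  Templates must be concrete; degenerate template bases are
rejected rather than matched by set intersection.
"""

from __future__ import annotations

import itertools
from typing import Iterable

__all__ = [
    "IUPAC_SETS",
    "SYMBOL_FOR",
    "COMPLEMENT",
    "DEFAULT_EXPANSION_CAP",
    "DegenerateSequence",
    "ConcreteSequence",
    "fold_degeneracy",
    "expand",
    "reverse_complement",
    "count_mismatches",
    "union_symbol",
]

#: symbol -> set of concrete bases it denotes (the 15-letter IUPAC alphabet;
#: gap characters are deliberately absent and rejected on input)
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: base set -> unique IUPAC symbol (inverse of IUPAC_SETS)
SYMBOL_FOR: dict[frozenset[str], str] = {s: sym for sym, s in IUPAC_SETS.items()}

_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: IUPAC-aware complement table (R<->Y, K<->M, B<->V, D<->H; S, W, N fixed)
COMPLEMENT: dict[str, str] = {
    sym: SYMBOL_FOR[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for sym, bases in IUPAC_SETS.items()
}

#: default bound on pool enumeration (see :func:`expand`)
DEFAULT_EXPANSION_CAP = 4096

_CONCRETE = frozenset("ACGT")


def _normalize(seq: str, *, allow_degenerate: bool = True) -> str:
    """Upper-case, map U->T, and validate against the IUPAC alphabet.

    Raises ValueError naming the offending character and its 1-based
    position; gap characters ('-', '.') are invalid here.
    """
    out = []
    for i, ch in enumerate(str(seq)):
        c = ch.upper()
        if c == "U":
            c = "T"
        if c not in IUPAC_SETS:
            raise ValueError(
                f"invalid nucleotide symbol {ch!r} at position {i + 1}"
            )
        if not allow_degenerate and c not in _CONCRETE:
            raise ValueError(
                f"degenerate symbol {ch!r} at position {i + 1} where a "
                "concrete A/C/G/T sequence is required"
            )
        out.append(c)
    return "".join(out)


class DegenerateSequence(str):
    """A validated sequence over the 15-letter IUPAC alphabet.

    Behaves as a plain ``str``; construction normalizes case and U->T and
    rejects non-IUPAC characters.
    """

    def __new__(cls, seq: str) -> "DegenerateSequence":
        return super().__new__(cls, _normalize(seq))

    def fold_degeneracy(self) -> int:
        return fold_degeneracy(self)

    def expand(self, cap: int = DEFAULT_EXPANSION_CAP) -> set["ConcreteSequence"]:
        return expand(self, cap)

    def reverse_complement(self) -> "DegenerateSequence":
        return reverse_complement(self)


class ConcreteSequence(str):
    """A validated nonempty sequence over {A, C, G, T} only."""

    def __new__(cls, seq: str) -> "ConcreteSequence":
        norm = _normalize(seq, allow_degenerate=False)
        if not norm:
            raise ValueError("a concrete sequence must have length >= 1")
        return super().__new__(cls, norm)

    def reverse_complement(self) -> "ConcreteSequence":
        return ConcreteSequence(reverse_complement(self))


def fold_degeneracy(seq: str) -> int:
    """Product over positions of the IUPAC set cardinality (>= 1)."""
    s = _normalize(seq)
    n = 1
    for ch in s:
        n *= len(IUPAC_SETS[ch])
    return n


def expand(seq: str, cap: int = DEFAULT_EXPANSION_CAP) -> set[ConcreteSequence]:
    """Enumerate the concrete pool a degenerate sequence denotes.

    Refuses (ValueError stating the degeneracy) when the pool exceeds
    ``cap``, to bound enumeration.
    """
    s = _normalize(seq)
    fold = fold_degeneracy(s)
    if fold > cap:
        raise ValueError(
            f"degeneracy {fold} exceeds the expansion cap {cap}"
        )
    pools = [sorted(IUPAC_SETS[ch]) for ch in s]
    return {ConcreteSequence("".join(p)) for p in itertools.product(*pools)}


def reverse_complement(seq: str) -> DegenerateSequence:
    """IUPAC-aware complement then reversal (an involution)."""
    s = _normalize(seq)
    return DegenerateSequence("".join(COMPLEMENT[ch] for ch in reversed(s)))


def count_mismatches(primer: str, window: str) -> int:
    """Positions where the concrete window base falls outside the primer set.

    Equals ``min(Hamming(e, window) for e in expand(primer))`` without
    enumerating the pool.  ``window`` must be concrete and the same length
    as ``primer``.
    """
    p = _normalize(primer)
    w = _normalize(window, allow_degenerate=False)
    if len(p) != len(w):
        raise ValueError(
            f"primer length {len(p)} != window length {len(w)}"
        )
    return sum(1 for pc, wc in zip(p, w) if wc not in IUPAC_SETS[pc])


def union_symbol(bases: Iterable[str]) -> str:
    """The unique IUPAC symbol for a nonempty subset of {A, C, G, T}."""
    bs = frozenset(_normalize(b, allow_degenerate=False) for b in bases)
    if not bs:
        raise ValueError("cannot encode an empty base set as an IUPAC symbol")
    for b in bs:
        if len(b) != 1:
            raise ValueError(f"expected single bases, got {b!r}")
    return SYMBOL_FOR[bs]
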