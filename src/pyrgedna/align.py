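"""Pairwise identity via semi-global alignment.

Identity throughout the pipeline means: matches / alignment columns,
excluding terminal gap columns, from a semi-global (end gaps free)
pairwise alignment, expressed as a percentage.  This mirrors how percent
identity is read off a BLAST-style local/semi-global hit when comparing an
amplicon against a reference that extends beyond it.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

__all__ = ["align_identity", "mismatch_distance"]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    # end gaps free on both sequences -> semi-global
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


@lru_cache(maxsize=200_000)
def align_identity(a: str, b: str) -> tuple[float, int]:
    """Return (identity %, aligned columns) for two concrete sequences.

    Terminal gap columns (the free end gaps of the semi-global alignment)
    are excluded from both the match count and the column count.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if a == b:  # fast path; also the common case for exact panel hits
        return 100.0, len(a)
    aln = _ALIGNER.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    n = len(row_a)
    i0 = 0
    while i0 < n and (row_a[i0] == "-" or row_b[i0] == "-"):
        i0 += 1
    i1 = n - 1
    while i1 >= 0 and (row_a[i1] == "-" or row_b[i1] == "-"):
        i1 -= 1
    if i1 < i0:  # no overlapping columns at all
        return 0.0, 0
    cols = i1 - i0 + 1
    matches = sum(
        1 for x, y in zip(row_a[i0 : i1 + 1], row_b[i0 : i1 + 1]) if x == y
    )
    return 100.0 * matches / cols, cols


def mismatch_distance(a: str, b: str) -> int:
    """Edit-style distance in base pairs between two near-identical sequences.

    Same-length pairs use the Hamming distance (cheap, exact for the 1-2 bp
    variant comparisons the curation rules make); otherwise the distance is
    derived from the semi-global alignment as non-match columns plus the
    length imbalance inside the aligned span.
    """
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)
    identity, cols = align_identity(a, b)
    mismatched = round(cols * (1.0 - identity / 100.0))
    return mismatched + abs(len(a) - len(b))
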