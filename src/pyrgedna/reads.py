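"""Amplicon read quality control, pair merging, and dereplication.

The QC stage applies, in order: degenerate-aware primer trimming, quality
truncation before the first base at or below the truncation score,
truncation to a maximum length, then rejection of reads with ambiguous
bases, more than the allowed expected errors (sum of per-base error
probabilities 10^(-Q/10)), or too short a remainder.  Defaults follow
common amplicon practice for this assay: maxEE 2, truncQ 4, 250 bp cap,
25 bp minimum.

Merging reverse-complements the reverse mate and joins on the longest
suffix/prefix overlap of at least ``min_overlap`` bases with at most
``max_overlap_mismatch`` mismatches (longest overlap wins ties).

Dereplication collapses identical merged sequences into an ASV x sample
count table.  This is a deliberate stand-in for an error-model denoiser:
the decision rules downstream (near-common collapse, low-abundance
corroboration) absorb the 1-2 bp error variants a denoiser would fold in,
and externally denoised tables can be loaded directly via AsvTable.read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .asvtable import AsvTable, assign_asv_ids
from .iupac import DegenerateSequence, count_mismatches, reverse_complement

__all__ = [
    "FastqRead",
    "QCParams",
    "QCReport",
    "expected_errors",
    "filter_and_trim",
    "qc_sample",
    "merge_pairs",
    "merge_sample",
    "dereplicate",
]


@dataclass(frozen=True)
class FastqRead:
    id: str
    sequence: str
    qualities: tuple[int, ...]  # Phred scores, already decoded

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class QCParams:
    max_expected_errors: float = 2.0
    trunc_quality: int = 4
    max_length: int = 250
    min_length_after_trim: int = 25
    primer: str | None = None  # degenerate primer expected as read prefix
    primer_max_mismatches: int = 0

    def __post_init__(self) -> None:
        if self.max_expected_errors <= 0 or self.trunc_quality < 0:
            raise ValueError("thresholds must be positive")
        if self.min_length_after_trim > self.max_length:
            raise ValueError("min length exceeds max length")


@dataclass
class QCReport:
    """Per-sample conservation accounting: reads_in == retained + rejected."""

    reads_in: int = 0
    retained: int = 0
    rejected: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return self.reads_in == self.retained + sum(self.rejected.values())


def expected_errors(quality_scores: Iterable[int]) -> float:
    """Sum of per-base error probabilities, 10^(-Q/10)."""
    total = 0.0
    for q in quality_scores:
        if q < 0:
            raise ValueError(f"negative Phred score {q}")
        total += 10.0 ** (-q / 10.0)
    return total


def filter_and_trim(
    read: FastqRead, params: QCParams
) -> tuple[FastqRead | None, str | None]:
    """Apply the QC pipeline to one read.

    Returns (trimmed read, None) on retention or (None, reason) on
    rejection; reasons are machine-readable codes: ``no_primer``,
    ``ambiguous``, ``max_ee``, ``too_short``.

    "Truncate at the first quality score of four" is implemented as
    truncation *before* the first base with Q <= trunc_quality, the common
    denoising convention.
    """
    seq, qual = read.sequence.upper(), list(read.qualities)

    if params.primer:
        primer = DegenerateSequence(params.primer)
        plen = len(primer)
        prefix = seq[:plen]
        if len(prefix) < plen or not set(prefix) <= set("ACGT"):
            return None, "no_primer"
        if count_mismatches(primer, prefix) > params.primer_max_mismatches:
            return None, "no_primer"
        seq, qual = seq[plen:], qual[plen:]

    cut = len(seq)
    for i, q in enumerate(qual):
        if q <= params.trunc_quality:
            cut = i
            break
    seq, qual = seq[:cut], qual[:cut]

    seq, qual = seq[: params.max_length], qual[: params.max_length]

    if len(seq) < params.min_length_after_trim:
        return None, "too_short"
    if any(c not in "ACGT" for c in seq):
        return None, "ambiguous"
    if expected_errors(qual) > params.max_expected_errors:
        return None, "max_ee"
    return FastqRead(read.id, seq, tuple(qual)), None


def qc_sample(
    reads: Iterable[FastqRead], params: QCParams
) -> tuple[list[FastqRead], QCReport]:
    """Filter a sample's reads with full conservation accounting."""
    report = QCReport()
    kept = []
    for read in reads:
        report.reads_in += 1
        out, reason = filter_and_trim(read, params)
        if out is None:
            report.rejected[reason] += 1
        else:
            report.retained += 1
            kept.append(out)
    return kept, report


def _longest_border(pattern: str, text: str, max_mismatch: int, min_len: int) -> int:
    """Longest L >= min_len with text[-L:] matching pattern[:L] (<= max_mismatch)."""
    limit = min(len(pattern), len(text))
    if max_mismatch == 0:
        # KMP failure function of pattern + '#' + text: final value is the
        # longest suffix of text equal to a prefix of pattern.
        s = pattern + "\x00" + text
        fail = [0] * len(s)
        k = 0
        for i in range(1, len(s)):
            while k and s[i] != s[k]:
                k = fail[k - 1]
            if s[i] == s[k]:
                k += 1
            fail[i] = k
        # walk the border chain to honor min_len and the length limit
        while k > limit:
            k = fail[k - 1]
        return k if k >= min_len else 0
    for length in range(limit, min_len - 1, -1):  # longest overlap wins
        mm = sum(
            1 for x, y in zip(text[-length:], pattern[:length]) if x != y
        )
        if mm <= max_mismatch:
            return length
    return 0


def merge_pairs(
    fwd: str,
    rev: str,
    min_overlap: int = 12,
    max_overlap_mismatch: int = 0,
) -> tuple[str | None, str | None]:
    """Merge a read pair on the best fwd-suffix / revcomp(rev)-prefix overlap.

    Returns (merged sequence, None) or (None, "no_overlap").
    """
    rc = str(reverse_complement(rev))
    if not set(fwd.upper()) <= set("ACGT") or not set(rc) <= set("ACGT"):
        raise ValueError("merge requires concrete reads (run QC first)")
    fwd = fwd.upper()
    best = _longest_border(rc, fwd, max_overlap_mismatch, min_overlap)
    if best == 0:
        return None, "no_overlap"
    return fwd + rc[best:], None


def merge_sample(
    pairs: Iterable[tuple[FastqRead, FastqRead]],
    min_overlap: int = 12,
    max_overlap_mismatch: int = 0,
) -> tuple[list[str], QCReport]:
    """Merge all retained pairs of a sample with conservation accounting."""
    report = QCReport()
    merged = []
    for f, r in pairs:
        report.reads_in += 1
        seq, reason = merge_pairs(
            f.sequence, r.sequence, min_overlap, max_overlap_mismatch
        )
        if seq is None:
            report.rejected[reason] += 1
        else:
            report.retained += 1
            merged.append(seq)
    return merged, report


def dereplicate(
    merged_by_sample: Mapping[str, Sequence[str]],
    samples: pd.DataFrame | None = None,
    min_count: int = 1,
) -> AsvTable:
    """Collapse identical merged sequences into an ASV x sample count table.

    ASV ids are assigned by total count descending (ties lexicographic by
    sequence).  ``min_count`` optionally drops ASVs whose total falls below
    it (default keeps everything, singletons included).
    """
    per_sample: dict[str, Counter] = {
        sample: Counter(str(s).upper() for s in seqs)
        for sample, seqs in merged_by_sample.items()
    }
    totals: Counter = Counter()
    for c in per_sample.values():
        totals.update(c)
    totals = Counter({s: n for s, n in totals.items() if n >= min_count})
    ids = assign_asv_ids(dict(totals))
    sample_ids = list(per_sample)
    counts = pd.DataFrame(
        0, index=[ids[s] for s in sorted(ids, key=lambda x: ids[x])],
        columns=sample_ids, dtype=int,
    )
    # reorder index numerically (ASV_1, ASV_2, ...)
    counts = counts.loc[sorted(counts.index, key=lambda a: int(a.split("_")[1]))]
    for sample, counter in per_sample.items():
        for seq, n in counter.items():
            if seq in ids:
                counts.loc[ids[seq], sample] = n
    sequences = {asv: seq for seq, asv in ids.items()}
    return AsvTable(sequences=sequences, counts=counts, samples=samples)
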