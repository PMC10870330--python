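"""Degeneracy-reduced primer design and mismatch-template screening.

Design follows the observed-states rule: a degenerate anchor primer is
narrowed (or, with a warning, widened) so that each position encodes
exactly the set of concrete bases observed at that alignment column in the
target group.  Robustness against unseen diversity is screened by building
hypothetical templates carrying an exact number of primer-template
mismatches at each priming site and reporting transparent mismatch
features (totals, per-site counts, 3'-proximal counts) for each template.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import (
    IUPAC_SETS,
    ConcreteSequence,
    DegenerateSequence,
    count_mismatches,
    fold_degeneracy,
    union_symbol,
)

__all__ = [
    "AlignmentWindow",
    "PrimerCandidate",
    "MismatchTemplate",
    "MismatchTemplateSet",
    "observed_state_sets",
    "reduce_degeneracy",
    "coverage_check",
    "generate_mismatch_templates",
    "mismatch_profile_report",
]

_GAPS = {"-", "."}
_CONCRETE = frozenset("ACGT")

#: default refusal threshold for exhaustive template enumeration
DEFAULT_TEMPLATE_CAP = 10**6


@dataclass(frozen=True)
class AlignmentWindow:
    """Per-column observed concrete-base sets over [start, end) of an alignment."""

    columns: tuple[frozenset[str], ...]
    start: int
    end: int

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class PrimerCandidate:
    sequence: DegenerateSequence
    orientation: str  # "forward" | "reverse"
    fold_degeneracy: int
    coverage: float | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MismatchTemplate:
    fwd_window: ConcreteSequence
    rev_window: ConcreteSequence
    k_fwd: int
    k_rev: int


@dataclass
class MismatchTemplateSet:
    fwd_primer: DegenerateSequence
    rev_primer: DegenerateSequence
    base_fwd: ConcreteSequence
    base_rev: ConcreteSequence
    templates: list[MismatchTemplate]
    mode: str
    seed: int | None
    warnings: list[str] = field(default_factory=list)


def observed_state_sets(
    aligned_sequences: list[str], start: int, end: int
) -> AlignmentWindow:
    """Collect the concrete bases observed at each column of a window.

    Gap characters and IUPAC ambiguity codes in the alignment rows are
    excluded from "observed": ambiguity in reference rows reflects
    sequencing uncertainty, not biology, and would inflate degeneracy.
    A column at which nothing concrete is observed is an error.
    """
    if not aligned_sequences:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in aligned_sequences}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    (row_len,) = lengths
    if not (0 <= start < end <= row_len):
        raise ValueError(f"window [{start}, {end}) outside alignment of length {row_len}")
    columns = []
    for col in range(start, end):
        observed = {
            row[col].upper()
            for row in aligned_sequences
            if row[col].upper() in _CONCRETE
        }
        if not observed:
            raise ValueError(
                f"alignment column {col} has no observed concrete base"
            )
        columns.append(frozenset(observed))
    return AlignmentWindow(tuple(columns), start, end)


def reduce_degeneracy(
    anchor: str, window: AlignmentWindow, orientation: str = "forward"
) -> PrimerCandidate:
    """Rewrite each anchor position as the union symbol of its observed bases.

    Positions where the observed set is not a subset of the anchor's set are
    reported as warnings (the primer is *widened* there), not errors:
    anchors are published primers and the target group may extend beyond
    the diversity they were designed against.
    """
    a = DegenerateSequence(anchor)
    if len(a) != len(window):
        raise ValueError(
            f"anchor length {len(a)} != window length {len(window)}"
        )
    letters = []
    warnings = []
    for i, (sym, observed) in enumerate(zip(a, window.columns)):
        letters.append(union_symbol(observed))
        if not observed <= IUPAC_SETS[sym]:
            warnings.append(
                f"position {i + 1}: observed {{{','.join(sorted(observed))}}} "
                f"not a subset of anchor '{sym}' "
                f"{{{','.join(sorted(IUPAC_SETS[sym]))}}}"
            )
    seq = DegenerateSequence("".join(letters))
    return PrimerCandidate(
        sequence=seq,
        orientation=orientation,
        fold_degeneracy=fold_degeneracy(seq),
        warnings=warnings,
    )


def coverage_check(primer: str, aligned_sequences: list[str]) -> pd.DataFrame:
    """Per-row mismatch counts of a primer against ungapped alignment rows.

    Rows containing a gap or ambiguity code within the primer window cannot
    be scored against a concrete template and are flagged ``unalignable``.
    Returned frame: columns ``row``, ``mismatches`` (nullable Int64),
    ``status``; attribute ``df.attrs["coverage"]`` holds the fraction of
    alignable rows with zero mismatches.
    """
    p = DegenerateSequence(primer)
    records = []
    for idx, row in enumerate(aligned_sequences):
        window = row.upper()
        if len(window) != len(p):
            raise ValueError(
                f"row {idx} length {len(window)} != primer length {len(p)}"
            )
        if set(window) <= _CONCRETE:
            records.append((idx, count_mismatches(p, window), "ok"))
        else:
            records.append((idx, pd.NA, "unalignable"))
    df = pd.DataFrame(records, columns=["row", "mismatches", "status"])
    df["mismatches"] = df["mismatches"].astype("Int64")
    ok = df[df["status"] == "ok"]
    df.attrs["coverage"] = (
        float((ok["mismatches"] == 0).mean()) if len(ok) else 0.0
    )
    return df


def _eligible_positions(primer: str) -> list[int]:
    # positions that can host a mismatch (an N position cannot)
    return [i for i, sym in enumerate(primer) if len(IUPAC_SETS[sym]) < 4]


def _off_choices(primer: str, i: int) -> list[str]:
    return sorted(_CONCRETE - IUPAC_SETS[primer[i]])


def count_windows_at_k(primer: str, k: int) -> int:
    """Closed-form census of distinct windows at exactly k mismatches.

    Sum over k-subsets of positions of the product of (4 - |set|) choices
    per chosen position.
    """
    p = DegenerateSequence(primer)
    if k == 0:
        return 1
    weights = [4 - len(IUPAC_SETS[sym]) for sym in p]
    total = 0
    for pos in itertools.combinations(range(len(p)), k):
        prod = 1
        for i in pos:
            prod *= weights[i]
        total += prod
    return total


def _enumerate_windows(primer: str, base: str, k: int) -> list[ConcreteSequence]:
    if k == 0:
        return [ConcreteSequence(base)]
    out = []
    elig = _eligible_positions(primer)
    for pos in itertools.combinations(elig, k):
        choices = [_off_choices(primer, i) for i in pos]
        for combo in itertools.product(*choices):
            w = list(base)
            for i, c in zip(pos, combo):
                w[i] = c
            out.append(ConcreteSequence("".join(w)))
    return out


def _sample_window(
    primer: str, base: str, k: int, rng: np.random.Generator
) -> ConcreteSequence:
    elig = _eligible_positions(primer)
    pos = rng.choice(len(elig), size=k, replace=False)
    w = list(base)
    for j in sorted(pos):
        i = elig[int(j)]
        choices = _off_choices(primer, i)
        w[i] = choices[int(rng.integers(len(choices)))]
    return ConcreteSequence("".join(w))


def generate_mismatch_templates(
    fwd: str,
    rev: str,
    base_fwd_window: str,
    base_rev_window: str,
    max_k: int = 3,
    mode: str = "enumerate",
    seed: int | None = None,
    sample_size: int = 50,
    template_cap: int = DEFAULT_TEMPLATE_CAP,
) -> MismatchTemplateSet:
    """Build hypothetical priming-site windows with exact mismatch counts.

    Windows are stored in primer orientation (the sequence each primer
    reads), so the primer 3' end is the last window position at both sites.
    Every emitted template is re-verified with :func:`count_mismatches`.

    ``enumerate`` emits every distinct (fwd, rev) window pair for each cell
    (k_fwd, k_rev) with 0 <= k <= max_k, excluding (0, 0); if the census
    exceeds ``template_cap`` the builder falls back to seeded sampling of
    ``sample_size`` pairs per cell and records a warning.
    """
    fwd_p = DegenerateSequence(fwd)
    rev_p = DegenerateSequence(rev)
    base_f = ConcreteSequence(base_fwd_window)
    base_r = ConcreteSequence(base_rev_window)
    for name, primer, base in (("forward", fwd_p, base_f), ("reverse", rev_p, base_r)):
        mm = count_mismatches(primer, base)
        if mm != 0:
            raise ValueError(
                f"{name} base window has {mm} mismatches; a 0-mismatch base is required"
            )
    if mode not in {"enumerate", "sample"}:
        raise ValueError(f"unknown mode {mode!r}")

    warnings = []
    if mode == "enumerate":
        counts_f = {k: count_windows_at_k(fwd_p, k) for k in range(max_k + 1)}
        counts_r = {k: count_windows_at_k(rev_p, k) for k in range(max_k + 1)}
        total = sum(
            counts_f[kf] * counts_r[kr]
            for kf in range(max_k + 1)
            for kr in range(max_k + 1)
            if (kf, kr) != (0, 0)
        )
        if total > template_cap:
            warnings.append(
                f"exhaustive census {total} exceeds cap {template_cap}; "
                f"falling back to seeded sampling ({sample_size}/cell)"
            )
            mode = "sample"

    templates: list[MismatchTemplate] = []
    if mode == "enumerate":
        win_f = {k: _enumerate_windows(fwd_p, base_f, k) for k in range(max_k + 1)}
        win_r = {k: _enumerate_windows(rev_p, base_r, k) for k in range(max_k + 1)}
        for kf in range(max_k + 1):
            for kr in range(max_k + 1):
                if (kf, kr) == (0, 0):
                    continue
                for wf in win_f[kf]:
                    for wr in win_r[kr]:
                        templates.append(MismatchTemplate(wf, wr, kf, kr))
    else:
        rng = np.random.default_rng(0 if seed is None else seed)
        for kf in range(max_k + 1):
            for kr in range(max_k + 1):
                if (kf, kr) == (0, 0):
                    continue
                for _ in range(sample_size):
                    wf = base_f if kf == 0 else _sample_window(fwd_p, base_f, kf, rng)
                    wr = base_r if kr == 0 else _sample_window(rev_p, base_r, kr, rng)
                    templates.append(MismatchTemplate(wf, wr, kf, kr))

    for t in templates:  # self-verification invariant
        if count_mismatches(fwd_p, t.fwd_window) != t.k_fwd:
            raise AssertionError("forward window mismatch count disagrees with label")
        if count_mismatches(rev_p, t.rev_window) != t.k_rev:
            raise AssertionError("reverse window mismatch count disagrees with label")

    return MismatchTemplateSet(
        fwd_primer=fwd_p,
        rev_primer=rev_p,
        base_fwd=base_f,
        base_rev=base_r,
        templates=templates,
        mode=mode,
        seed=seed,
        warnings=warnings,
    )


def _mismatch_positions(primer: str, window: str) -> list[int]:
    return [
        i for i, (pc, wc) in enumerate(zip(primer, window))
        if wc not in IUPAC_SETS[pc]
    ]


def mismatch_profile_report(
    template_set: MismatchTemplateSet, three_prime_window: int = 5
) -> pd.DataFrame:
    """Tabulate mismatch features per hypothetical template.

    Amplification-probability prediction is out of scope here; the report
    instead exposes the features any predictor (or a reviewer) needs: the
    per-site and total mismatch counts and how many mismatches fall within
    ``three_prime_window`` positions of each primer's 3' end, where
    extension is most sensitive.
    """
    rows = []
    fp, rp = template_set.fwd_primer, template_set.rev_primer
    for idx, t in enumerate(template_set.templates):
        mf = _mismatch_positions(fp, t.fwd_window)
        mr = _mismatch_positions(rp, t.rev_window)
        rows.append(
            {
                "template": idx,
                "fwd_window": str(t.fwd_window),
                "rev_window": str(t.rev_window),
                "k_fwd": t.k_fwd,
                "k_rev": t.k_rev,
                "total": t.k_fwd + t.k_rev,
                "fwd_3prime": sum(1 for i in mf if i >= len(fp) - three_prime_window),
                "rev_3prime": sum(1 for i in mr if i >= len(rp) - three_prime_window),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "template", "fwd_window", "rev_window",
            "k_fwd", "k_rev", "total", "fwd_3prime", "rev_3prime",
        ],
    )
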