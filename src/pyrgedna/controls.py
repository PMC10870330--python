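"""Exogenous positive PCR control construction and inhibition calling.

An internal amplification control distinguishes "no target present" from
"PCR inhibited".  The control is an exogenous insert (by design from a
taxon no contemporary lab handles; the packaged default derives from
synthetic thylacine mitochondrial sequence) flanked by concrete priming
sites compatible with the degenerate assay primers, sized so its amplicon
runs a fixed offset (default 100 bp) shorter than a true target amplicon
and is therefore separable on an agarose gel.

Replicate calling: reactions run in quadruplicate with the control spiked
into exactly one.  If nothing amplifies anywhere (including the spiked
replicate) the sample is INHIBITED; if only the spiked replicate amplifies
and at the control length, the sample is uninhibited but target-negative;
any band at the target length makes the sample a candidate positive (the
spiked replicate then shows a double band).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .align import align_identity
from .iupac import (
    ConcreteSequence,
    DegenerateSequence,
    count_mismatches,
    expand,
    reverse_complement,
)

__all__ = [
    "THYLACINE_CONTROL",
    "PositiveControl",
    "ReplicateObservation",
    "InhibitionCall",
    "ControlValidation",
    "build_control",
    "validate_control",
    "classify_inhibition",
]

#: packaged synthetic positive-control amplicon (thylacine-derived insert
#: flanked by 20 bp concrete priming sites compatible with the default
#: degenerate COI primers); 255 bp.
THYLACINE_CONTROL = ConcreteSequence(
    "ACTGGGTGGACCGTGTATCCTCATCACAACAATTATCAATATAAAACCTCCAGCCCTATCC"
    "CAATATCAAACTCCATTATTTGTTTGATCAGTAATAATTACAGCAGTACTTCTACTATTAT"
    "CCTTACCCGTTCTGGCAGCAGGCATTACAATACTACTTACGGACCGAAATCTTAATACAAC"
    "ATTTTTTGACCCTGCTGGAGGAGGTGACCCAATCCTTTATCAACATCTATTTTGATTTTTT"
    "GGTCACCCTGA"
)

#: exogeneity gate: maximum tolerated identity of the insert to any panel
#: reference (the control must be unmistakable from targets in sequence space)
DEFAULT_EXOGENEITY_IDENTITY = 75.0


@dataclass(frozen=True)
class PositiveControl:
    insert: ConcreteSequence
    fwd_site: ConcreteSequence
    rev_site: ConcreteSequence

    @property
    def full_sequence(self) -> ConcreteSequence:
        return ConcreteSequence(self.fwd_site + self.insert + self.rev_site)

    def __len__(self) -> int:
        return len(self.fwd_site) + len(self.insert) + len(self.rev_site)


@dataclass(frozen=True)
class ReplicateObservation:
    replicate_id: str
    has_control: bool
    bands: tuple[int, ...]  # observed product lengths, bp


class InhibitionCall(enum.Enum):
    INHIBITED = "INHIBITED"
    NEGATIVE_UNINHIBITED = "NEGATIVE_UNINHIBITED"
    CANDIDATE_POSITIVE = "CANDIDATE_POSITIVE"


@dataclass
class ControlValidation:
    fwd_mismatches: int
    rev_mismatches: int
    length_offset: int | None
    max_panel_identity: float | None
    passed: bool
    notes: list[str] = field(default_factory=list)


def _default_site(primer: DegenerateSequence) -> ConcreteSequence:
    # deterministic choice among the 0-mismatch expansions
    return min(expand(primer))


def build_control(
    insert: str,
    fwd_primer: str,
    rev_primer: str,
    reference_amplicon_length: int,
    delta: int = 100,
    fwd_site: str | None = None,
    rev_site: str | None = None,
    panel_sequences: dict[str, str] | None = None,
    max_panel_identity: float = DEFAULT_EXOGENEITY_IDENTITY,
) -> PositiveControl:
    """Assemble a positive control ``delta`` bp shorter than the target amplicon.

    Priming sites default to deterministic 0-mismatch expansions of the
    primers (the plus-strand 3' site is an expansion of the reverse
    complement of the reverse primer).  The insert is truncated from its 3'
    end to hit the requested control length and checked for exogeneity
    against the reference panel when one is supplied.
    """
    fwd_p = DegenerateSequence(fwd_primer)
    rev_p = DegenerateSequence(rev_primer)
    fsite = ConcreteSequence(fwd_site) if fwd_site else _default_site(fwd_p)
    rsite = (
        ConcreteSequence(rev_site)
        if rev_site
        else _default_site(reverse_complement(rev_p))
    )
    if count_mismatches(fwd_p, fsite) != 0:
        raise ValueError("forward priming site is not a 0-mismatch expansion")
    if count_mismatches(reverse_complement(rev_p), rsite) != 0:
        raise ValueError("reverse priming site is not a 0-mismatch expansion")

    control_len = reference_amplicon_length - delta
    insert_len = control_len - len(fsite) - len(rsite)
    ins = ConcreteSequence(insert)
    if insert_len < 1:
        raise ValueError(
            f"requested control length {control_len} leaves no room for an insert"
        )
    if len(ins) < insert_len:
        raise ValueError(
            f"insert length {len(ins)} is too short for the requested "
            f"control length (needs {insert_len})"
        )
    ins = ConcreteSequence(ins[:insert_len])
    if panel_sequences:
        worst = max(align_identity(ins, ref)[0] for ref in panel_sequences.values())
        if worst >= max_panel_identity:
            raise ValueError(
                f"not exogenous: insert shares {worst:.1f}% identity with a "
                f"panel reference (gate < {max_panel_identity:.1f}%)"
            )
    return PositiveControl(insert=ins, fwd_site=fsite, rev_site=rsite)


def validate_control(
    control: PositiveControl | str,
    fwd_primer: str,
    rev_primer: str,
    panel_sequences: dict[str, str] | None = None,
    delta_expected: int = 100,
    reference_amplicon_length: int | None = None,
    max_panel_identity: float = DEFAULT_EXOGENEITY_IDENTITY,
) -> ControlValidation:
    """Report priming-site mismatches, length offset, and exogeneity.

    Passes iff both priming sites have 0 mismatches, the length offset
    equals ``delta_expected`` (when a reference length is given), and the
    control stays below the exogeneity identity gate (when a panel is given).
    """
    fwd_p = DegenerateSequence(fwd_primer)
    rev_p = DegenerateSequence(rev_primer)
    seq = (
        control.full_sequence
        if isinstance(control, PositiveControl)
        else ConcreteSequence(control)
    )
    notes = []
    if len(seq) < len(fwd_p) + len(rev_p):
        raise ValueError("control shorter than the two priming sites combined")
    fwd_mm = count_mismatches(fwd_p, seq[: len(fwd_p)])
    rev_mm = count_mismatches(reverse_complement(rev_p), seq[-len(rev_p):])

    offset = None
    if reference_amplicon_length is not None:
        offset = reference_amplicon_length - len(seq)
        if offset != delta_expected:
            notes.append(
                f"length offset {offset} != expected {delta_expected}"
            )
    max_id = None
    if panel_sequences:
        max_id = max(align_identity(seq, ref)[0] for ref in panel_sequences.values())
        if max_id >= max_panel_identity:
            notes.append(
                f"not exogenous: {max_id:.1f}% identity to a panel reference"
            )
    if fwd_mm:
        notes.append(f"forward priming site has {fwd_mm} mismatches")
    if rev_mm:
        notes.append(f"reverse priming site has {rev_mm} mismatches")
    passed = (
        fwd_mm == 0
        and rev_mm == 0
        and (offset is None or offset == delta_expected)
        and (max_id is None or max_id < max_panel_identity)
    )
    return ControlValidation(
        fwd_mismatches=fwd_mm,
        rev_mismatches=rev_mm,
        length_offset=offset,
        max_panel_identity=max_id,
        passed=passed,
        notes=notes,
    )


def classify_inhibition(
    observations: list[ReplicateObservation],
    target_len: int,
    control_len: int,
    tolerance: int = 20,
) -> InhibitionCall:
    """Classify a sample's PCR replicate set into the 3-state partition.

    ``tolerance`` is the band-length resolution of the gel (default
    +/- 20 bp, agarose-scale; the assay separates control and target by
    100 bp).  The function is total: every observation set maps to exactly
    one state.
    """
    spiked = [o for o in observations if o.has_control]
    if len(spiked) != 1:
        raise ValueError(
            f"exactly one replicate must carry the positive control "
            f"(got {len(spiked)})"
        )
    all_bands = [b for o in observations for b in o.bands]
    if any(abs(b - target_len) <= tolerance for b in all_bands):
        return InhibitionCall.CANDIDATE_POSITIVE
    if not all_bands:
        return InhibitionCall.INHIBITED
    return InhibitionCall.NEGATIVE_UNINHIBITED
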