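"""Synthetic amplicon study generator with full ground truth.

Emulates the statistical structure the curation rules assume: a panel of
divergent COI lineages whose references carry exact expansions of the
degenerate primers at their ends; a two-region landscape far enough apart
to exercise the long-distance contamination rule, with amplification
batches spanning regions; per-sample paired reads in which one dominant
haplotype carries ~85%-95% of target reads and minor haplotypes split the
remainder geometrically; i.i.d. per-base substitution error; PCR-junction
chimeras between a resident haplotype and a co-occurring non-target
background sequence; batch-correlated cross-site contamination at
log-uniform read counts; and fully negative sites that receive only
background.  Every emitted read pair is traceable to a template in the
ground truth.

Two modelling conventions worth knowing: chimera and contamination reads
are emitted error-free (both are clonal PCR products -- a junction
artifact amplified from an early cycle, and carry-over of an already
amplified product -- so their dereplicated sequences equal their templates
exactly, which is precisely the signature the curation rules key on), and
each occupied site captures target DNA with probability
``detection_prob``, modelling imperfect field detection independent of
sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asvtable import AsvTable
from .curation import haversine_miles
from .iupac import IUPAC_SETS, reverse_complement
from .panel import ReferencePanel, ReferenceRecord
from .reads import FastqRead

__all__ = [
    "DEFAULT_FORWARD_PRIMER",
    "DEFAULT_REVERSE_PRIMER",
    "SimConfig",
    "GroundTruth",
    "ChimeraEvent",
    "ContaminationEvent",
    "simulate_reference_panel",
    "simulate_landscape",
    "simulate_sample_reads",
    "simulate_conventional_surveys",
    "evaluate_pipeline",
]

#: degenerate COI primers targeting the springsnail 3' COI fragment
#: (BF1/BR2 family, degeneracy-reduced to the target group)
DEFAULT_FORWARD_PRIMER = "ACBGGRTGRACYGTRTAYCC"
DEFAULT_REVERSE_PRIMER = "TCDGGRTGHCCRAARAAYCA"

_BASES = np.frombuffer(b"ACGT", np.uint8)


@dataclass
class SimConfig:
    n_lineages: int = 4
    amplicon_length: int = 316
    lineage_divergence: float = 0.05      # target pairwise p-distance
    haplotypes_per_lineage: int = 3       # 1 dominant + minors, 1-2 bp apart
    n_sites: int = 20
    occupancy_prob: float = 0.5
    #: two region box centers (lat, lon); must be farther apart than the
    #: contamination distance rule for that rule to be exercisable
    region_centers: tuple[tuple[float, float], ...] = (
        (39.5, -118.2),
        (31.5, -110.3),
    )
    region_halfwidth_miles: float = 20.0
    n_batches: int = 4
    reads_per_sample: int = 50_000
    read_length: int = 250
    dominant_fraction: tuple[float, float] = (0.85, 0.95)
    minor_ratio: float = 0.5              # geometric decay among minors
    error_rate: float = 0.001             # per-base substitution
    chimera_fraction: float = 0.005       # of an occupied sample's reads
    chimeras_per_sample: int = 3
    #: fraction of chimera junctions drawn inside a terminal zone (template
    #: switching concentrates near fragment ends, which is the artifact
    #: class the terminal-window curation rule targets); the rest uniform
    chimera_terminal_bias: float = 0.5
    chimera_terminal_zone: int = 60       # bp from either inner end
    background_fraction: float = 0.2      # of an occupied sample's reads
    backgrounds_per_site: int = 2
    contamination_events: int = 3
    contamination_reads: tuple[int, int] = (1, 2000)  # log-uniform
    detection_prob: float = 0.9           # P(occupied sample captures target)
    fwd_primer: str = DEFAULT_FORWARD_PRIMER
    rev_primer: str = DEFAULT_REVERSE_PRIMER

    def __post_init__(self) -> None:
        for r in (
            self.occupancy_prob, self.error_rate, self.chimera_fraction,
            self.background_fraction, self.detection_prob,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.amplicon_length <= len(self.fwd_primer) + len(self.rev_primer):
            raise ValueError("amplicon shorter than the two priming sites")


@dataclass(frozen=True)
class ChimeraEvent:
    sample: str
    site: str
    parent_core: str      # template id supplying the core
    parent_window: str    # template id supplying the foreign segment
    breakpoint: int       # inner-sequence coordinate, 0-based
    arrangement: str      # "core-first" | "window-first"
    template: str         # full amplicon sequence
    n_reads: int


@dataclass(frozen=True)
class ContaminationEvent:
    asv_sequence: str     # inner (primer-trimmed) sequence
    source_site: str
    source_sample: str
    batch: str
    target_site: str
    target_sample: str
    n_reads: int


@dataclass
class GroundTruth:
    #: site -> lineage id (None for unoccupied)
    occupancy: dict[str, str | None]
    #: site -> {haplotype id -> inner sequence} for residents
    resident_haplotypes: dict[str, dict[str, str]]
    #: sample -> whether target DNA was captured (detection_prob draw)
    captured: dict[str, bool]
    #: sample -> {template id -> reads emitted}
    template_reads: dict[str, dict[str, int]]
    #: template id -> full amplicon sequence
    templates: dict[str, str]
    chimera_events: list[ChimeraEvent] = field(default_factory=list)
    contamination_events: list[ContaminationEvent] = field(default_factory=list)


# --------------------------------------------------------------------- panel


def _sample_expansion(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(IUPAC_SETS[sym])[rng.integers(len(IUPAC_SETS[sym]))]
        for sym in primer
    )


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        old = out[p]
        choices = [b for b in "ACGT" if b != old]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def simulate_reference_panel(
    config: SimConfig, seed: int
) -> tuple[ReferencePanel, dict[str, int]]:
    """Generate named lineage references with landscape-consistent localities.

    All references share exact primer-site ends (so every reference is
    amplifiable with 0 mismatches) and differ in the inner region at the
    configured pairwise divergence.  Lineages alternate between the two
    region boxes; each lineage's known locality is its region box center,
    which places every same-region site within the default corroboration
    radius.  Returns (panel, lineage -> region index).
    """
    rng = np.random.default_rng(seed)
    L = config.amplicon_length
    fwd_site = _sample_expansion(config.fwd_primer, rng)
    rev_site = str(reverse_complement(_sample_expansion(config.rev_primer, rng)))
    inner_len = L - len(fwd_site) - len(rev_site)
    n_mut = round(config.lineage_divergence / 2.0 * L)
    if n_mut > inner_len:
        raise ValueError(
            f"divergence {config.lineage_divergence} unattainable: needs "
            f"{n_mut} inner mutations but only {inner_len} inner positions"
        )
    root = _random_seq(inner_len, rng)
    records = []
    lineage_region: dict[str, int] = {}
    for i in range(config.n_lineages):
        positions = rng.choice(inner_len, size=n_mut, replace=False)
        inner = _mutate(root, positions, rng)
        region = i % len(config.region_centers)
        name = f"L{i + 1}"
        records.append(
            ReferenceRecord(
                id=f"REF_{name}",
                taxon=f"P. simulata {name}",
                sequence=fwd_site + inner + rev_site,
                localities=(config.region_centers[region],),
            )
        )
        lineage_region[f"REF_{name}"] = region
    return ReferencePanel(records), lineage_region


# ----------------------------------------------------------------- landscape


def simulate_landscape(
    config: SimConfig,
    panel: ReferencePanel,
    lineage_region: dict[str, int],
    seed: int,
) -> tuple[pd.DataFrame, dict[str, str | None]]:
    """Place sites in the region boxes and draw occupancy.

    Sites alternate between regions; amplification batches are assigned
    round-robin over the interleaved site order so every batch spans both
    regions (making the same-batch contamination rule exercisable).
    Occupied sites draw a resident lineage from their own region.
    Returns (sites frame indexed by site id with latitude/longitude/batch,
    occupancy truth site -> lineage reference id or None).
    """
    rng = np.random.default_rng(seed)
    rows = []
    occupancy: dict[str, str | None] = {}
    lineages_by_region: dict[int, list[str]] = {}
    for ref_id, region in lineage_region.items():
        lineages_by_region.setdefault(region, []).append(ref_id)
    for i in range(config.n_sites):
        region = i % len(config.region_centers)
        clat, clon = config.region_centers[region]
        dlat = config.region_halfwidth_miles / 69.0
        dlon = config.region_halfwidth_miles / (
            69.0 * np.cos(np.radians(clat))
        )
        lat = clat + rng.uniform(-dlat, dlat)
        lon = clon + rng.uniform(-dlon, dlon)
        site = f"SITE_{i + 1:03d}"
        rows.append(
            {
                "site": site,
                "latitude": round(float(lat), 6),
                "longitude": round(float(lon), 6),
                # group consecutive sites (one per region) into a batch so
                # every batch spans both regions
                "batch": f"BATCH_{(i // len(config.region_centers)) % config.n_batches + 1}",
            }
        )
        if rng.random() < config.occupancy_prob and lineages_by_region.get(region):
            pool = lineages_by_region[region]
            occupancy[site] = pool[rng.integers(len(pool))]
        else:
            occupancy[site] = None
    sites = pd.DataFrame(rows).set_index("site")
    return sites, occupancy


# --------------------------------------------------------------------- reads


def _emit_pairs(
    template_ids: list[str],
    templates: dict[str, str],
    counts: dict[str, int],
    with_error: dict[str, bool],
    sample: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[FastqRead], list[FastqRead], dict[str, int]]:
    """Vectorized read-pair emission; returns (R1, R2, per-template counts)."""
    order = [tid for tid in template_ids for _ in range(counts[tid])]
    rng.shuffle(order)
    r1, r2 = [], []
    rl = config.read_length
    for idx, tid in enumerate(order):
        amp = templates[tid]
        arr = np.frombuffer(amp.encode(), np.uint8).copy()
        fwd = arr[:rl]
        rc = np.frombuffer(
            str(reverse_complement(amp)).encode(), np.uint8
        ).copy()
        rev = rc[:rl]
        if with_error[tid] and config.error_rate > 0:
            for mate in (fwd, rev):
                mask = rng.random(len(mate)) < config.error_rate
                n_err = int(mask.sum())
                if n_err:
                    shifts = rng.integers(1, 4, n_err)
                    idxs = np.flatnonzero(mask)
                    cur = np.searchsorted(_BASES, mate[idxs])
                    mate[idxs] = _BASES[(cur + shifts) % 4]
        # quality: Q38 body, occasionally a Q2 tail to exercise truncation
        for mate_arr, mate_no, out in ((fwd, 1, r1), (rev, 2, r2)):
            n = len(mate_arr)
            qual = [38] * n
            if rng.random() < 0.3:
                tail = int(rng.integers(1, 12))
                tail = min(tail, n)
                qual[n - tail:] = [2] * tail
            out.append(
                FastqRead(
                    id=f"{sample}:{idx}/{mate_no}",
                    sequence=mate_arr.tobytes().decode(),
                    qualities=tuple(qual),
                )
            )
    emitted = {tid: 0 for tid in template_ids}
    for tid in order:
        emitted[tid] += 1
    return r1, r2, emitted


def simulate_sample_reads(
    config: SimConfig,
    panel: ReferencePanel,
    sites: pd.DataFrame,
    occupancy: dict[str, str | None],
    seed: int,
) -> tuple[dict[str, tuple[list[FastqRead], list[FastqRead]]], GroundTruth]:
    """Emit paired FASTQ reads per sample (one sample per site) plus truth.

    Per occupied, capturing sample the depth splits into: contamination
    copies injected by batch-correlated events, chimeric junction reads,
    background (non-target) reads, and target reads in which the dominant
    haplotype draws a Uniform(dominant_fraction) share and minors decay
    geometrically.  Unoccupied (or non-capturing) samples receive only
    background.  Conservation: every sample emits exactly
    ``reads_per_sample`` pairs.
    """
    rng = np.random.default_rng(seed)
    L = config.amplicon_length
    ref_seq = panel.sequences
    fwd_len = len(config.fwd_primer)
    rev_len = len(config.rev_primer)

    samples = {site: f"{site}_S1" for site in sites.index.astype(str)}
    sample_site = {v: k for k, v in samples.items()}
    batches = {s: str(sites.loc[site, "batch"]) for site, s in samples.items()}

    # resident haplotypes: dominant = lineage reference; minors 1-2 bp off
    templates: dict[str, str] = {}
    resident: dict[str, dict[str, str]] = {}
    site_templates: dict[str, dict[str, list[str]]] = {}
    for site in sites.index.astype(str):
        lineage = occupancy[site]
        tlist: list[str] = []
        if lineage is not None:
            base = ref_seq[lineage]
            inner = base[fwd_len: L - rev_len]
            haps = {f"{site}:{lineage}:H1": base}
            for h in range(2, config.haplotypes_per_lineage + 1):
                n_mut = int(rng.integers(1, 3))  # 1-2 bp within-lineage
                pos = rng.choice(len(inner), size=n_mut, replace=False)
                mut_inner = _mutate(inner, pos, rng)
                haps[f"{site}:{lineage}:H{h}"] = (
                    base[:fwd_len] + mut_inner + base[L - rev_len:]
                )
            templates.update(haps)
            resident[site] = {
                hid: seq[fwd_len: L - rev_len] for hid, seq in haps.items()
            }
            tlist = list(haps)
        else:
            resident[site] = {}
        bg = []
        for b in range(config.backgrounds_per_site):
            bid = f"{site}:BG{b + 1}"
            templates[bid] = (
                _sample_expansion(config.fwd_primer, rng)
                + _random_seq(L - fwd_len - rev_len, rng)
                + str(reverse_complement(_sample_expansion(config.rev_primer, rng)))
            )
            bg.append(bid)
        site_templates[site] = {"target": tlist, "background": bg}

    captured = {
        s: bool(occupancy[sample_site[s]] is not None
                and rng.random() < config.detection_prob)
        for s in samples.values()
    }

    # contamination events: copy a source sample's dominant inner sequence
    # into same-batch samples at sites beyond the distance rule
    contamination: list[ContaminationEvent] = []
    contam_extra: dict[str, list[tuple[str, int]]] = {s: [] for s in samples.values()}
    occupied_capturing = [
        s for s in samples.values()
        if occupancy[sample_site[s]] is not None and captured[s]
    ]
    lo, hi = config.contamination_reads
    for _ in range(config.contamination_events):
        if not occupied_capturing:
            break
        src = occupied_capturing[rng.integers(len(occupied_capturing))]
        src_site = sample_site[src]
        dom_tid = site_templates[src_site]["target"][0]
        here = (
            float(sites.loc[src_site, "latitude"]),
            float(sites.loc[src_site, "longitude"]),
        )
        candidates = [
            s for s in samples.values()
            if s != src
            and batches[s] == batches[src]
            and haversine_miles(
                here,
                (float(sites.loc[sample_site[s], "latitude"]),
                 float(sites.loc[sample_site[s], "longitude"])),
            ) > 500.0
        ]
        if not candidates:
            continue
        tgt = candidates[rng.integers(len(candidates))]
        n = int(np.exp(rng.uniform(np.log(lo), np.log(hi + 1))))
        n = max(lo, min(n, hi))
        contam_extra[tgt].append((dom_tid, n))
        contamination.append(
            ContaminationEvent(
                asv_sequence=templates[dom_tid][fwd_len: L - rev_len],
                source_site=src_site,
                source_sample=src,
                batch=batches[src],
                target_site=sample_site[tgt],
                target_sample=tgt,
                n_reads=n,
            )
        )

    reads_out: dict[str, tuple[list[FastqRead], list[FastqRead]]] = {}
    truth = GroundTruth(
        occupancy=dict(occupancy),
        resident_haplotypes=resident,
        captured=captured,
        template_reads={},
        templates=templates,
        contamination_events=contamination,
    )

    for site in sites.index.astype(str):
        sample = samples[site]
        D = config.reads_per_sample
        contam = contam_extra[sample]
        n_contam = sum(n for _, n in contam)
        if n_contam >= D:  # carve contamination out of the fixed depth
            scale = (D - 1) / n_contam
            contam = [(t, max(1, int(n * scale))) for t, n in contam]
            n_contam = sum(n for _, n in contam)
        remaining = D - n_contam

        tlist = site_templates[site]["target"]
        bglist = site_templates[site]["background"]
        counts: dict[str, int] = {}
        with_error: dict[str, bool] = {}
        chim_events_here: list[ChimeraEvent] = []

        if tlist and captured[sample]:
            n_chim_total = round(config.chimera_fraction * remaining)
            chim_templates: dict[str, str] = {}
            if n_chim_total > 0 and config.chimeras_per_sample > 0:
                per = np.bincount(
                    rng.integers(config.chimeras_per_sample, size=n_chim_total),
                    minlength=config.chimeras_per_sample,
                )
                dom_tid = tlist[0]
                dom_inner = templates[dom_tid][fwd_len: L - rev_len]
                fwd_site = templates[dom_tid][:fwd_len]
                rev_site = templates[dom_tid][L - rev_len:]
                for ci, n_reads in enumerate(per):
                    if n_reads == 0:
                        continue
                    bid = bglist[int(rng.integers(len(bglist)))]
                    bg_inner = templates[bid][fwd_len: L - rev_len]
                    n_inner = len(dom_inner)
                    arrangement = (
                        "core-first" if rng.random() < 0.5 else "window-first"
                    )
                    if rng.random() < config.chimera_terminal_bias:
                        # junction inside the terminal zone: foreign
                        # segment 15..zone bp at the appropriate end
                        zone = min(config.chimera_terminal_zone, n_inner - 16)
                        foreign = int(rng.integers(15, zone + 1))
                        bp = (
                            n_inner - foreign
                            if arrangement == "core-first"
                            else foreign
                        )
                    else:
                        bp = int(rng.integers(1, n_inner))
                    if arrangement == "core-first":
                        inner = dom_inner[:bp] + bg_inner[bp:]
                    else:
                        inner = bg_inner[:bp] + dom_inner[bp:]
                    tid = f"{site}:CHIM{ci + 1}"
                    chim_templates[tid] = fwd_site + inner + rev_site
                    chim_events_here.append(
                        ChimeraEvent(
                            sample=sample,
                            site=site,
                            parent_core=dom_tid,
                            parent_window=bid,
                            breakpoint=bp,
                            arrangement=arrangement,
                            template=chim_templates[tid],
                            n_reads=int(n_reads),
                        )
                    )
                    counts[tid] = int(n_reads)
                    with_error[tid] = False
            templates.update(chim_templates)
            n_chim = sum(counts.values())
            n_bg = round(config.background_fraction * remaining)
            n_target = remaining - n_chim - n_bg
            dom_frac = rng.uniform(*config.dominant_fraction)
            shares = [dom_frac]
            minors = tlist[1:]
            if minors:
                raw = np.array(
                    [config.minor_ratio**j for j in range(len(minors))]
                )
                raw = raw / raw.sum() * (1.0 - dom_frac)
                shares.extend(raw.tolist())
            probs = np.array(shares) / sum(shares)
            tcounts = rng.multinomial(n_target, probs)
            for tid, n in zip(tlist, tcounts):
                counts[tid] = int(n)
                with_error[tid] = True
            bcounts = rng.multinomial(
                n_bg, np.full(len(bglist), 1.0 / len(bglist))
            )
            for bid, n in zip(bglist, bcounts):
                counts[bid] = int(n)
                with_error[bid] = True
        else:
            bcounts = rng.multinomial(
                remaining, np.full(len(bglist), 1.0 / len(bglist))
            )
            for bid, n in zip(bglist, bcounts):
                counts[bid] = int(n)
                with_error[bid] = True

        for tid, n in contam:
            counts[tid] = counts.get(tid, 0) + n
            with_error.setdefault(tid, False)

        r1, r2, emitted = _emit_pairs(
            list(counts), templates, counts, with_error, sample, config, rng
        )
        reads_out[sample] = (r1, r2)
        truth.template_reads[sample] = emitted
        truth.chimera_events.extend(chim_events_here)

    return reads_out, truth


def simulate_conventional_surveys(
    sites: pd.DataFrame,
    occupancy: dict[str, str | None],
    seed: int,
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020),
    per_visit_detection: float = 0.7,
) -> pd.DataFrame:
    """Timed-search survey records: occupied sites detected imperfectly per visit."""
    rng = np.random.default_rng(seed)
    rows = []
    for site in sites.index.astype(str):
        n_visits = int(rng.integers(1, 5))
        visit_years = sorted(
            rng.choice(years, size=n_visits, replace=False).tolist()
        )
        for y in visit_years:
            detected = (
                occupancy[site] is not None
                and rng.random() < per_visit_detection
            )
            rows.append({"site": site, "year": int(y), "detected": bool(detected)})
    return pd.DataFrame(rows, columns=["site", "year", "detected"])


# ---------------------------------------------------------------- evaluation


def _confusion(tp: int, fn: int, fp: int, tn: int | None = None) -> dict:
    out = {"tp": tp, "fn": fn, "fp": fp}
    out["sensitivity"] = tp / (tp + fn) if tp + fn else float("nan")
    if tn is not None:
        out["tn"] = tn
        out["specificity"] = tn / (tn + fp) if tn + fp else float("nan")
    return out


def terminal_chimera_truth(
    truth: GroundTruth,
    config: SimConfig,
    panel: "ReferencePanel",
    terminal_window: int = 60,
    window_max_identity: float = 90.0,
    min_identity: float = 75.0,
) -> list[tuple[str, str]]:
    """(inner sequence, site) of injected chimeras the terminal rule targets.

    A chimera qualifies when its foreign segment is confined to a terminal
    window (so the core is exactly the dominant haplotype's), the window
    is divergent enough from the dominant's window to clear the rule's
    identity ceiling (positional identity: the windows occupy the same
    region by construction), and the window does not substantially derive
    from the parent's own lineage -- short foreign tails leave the window
    best-hitting the parent's reference, and the rule correctly declines
    to call those.
    """
    from .curation import best_reference_hit

    fwd_len = len(config.fwd_primer)
    rev_len = len(config.rev_primer)
    L = config.amplicon_length

    def pos_ident(x: str, y: str) -> float:
        return 100.0 * sum(1 for a, b in zip(x, y) if a == b) / len(x)

    out = []
    for ev in truth.chimera_events:
        inner = ev.template[fwd_len: L - rev_len]
        dom_inner = truth.templates[ev.parent_core][fwd_len: L - rev_len]
        n = len(inner)
        w = terminal_window
        window = None
        if ev.arrangement == "core-first" and ev.breakpoint >= n - w:
            if pos_ident(inner[-w:], dom_inner[-w:]) < window_max_identity:
                window = inner[-w:]
        elif ev.arrangement == "window-first" and ev.breakpoint <= w:
            if pos_ident(inner[:w], dom_inner[:w]) < window_max_identity:
                window = inner[:w]
        if window is None or inner == dom_inner:
            continue
        parent_hit = best_reference_hit(dom_inner, panel)
        win_hit = best_reference_hit(window, panel)
        foreign = not (
            win_hit.ref_id == parent_hit.ref_id
            and win_hit.identity >= min_identity
            and win_hit.aligned_length >= 0.8 * w
        )
        if foreign:
            out.append((inner, ev.site))
    return out


def evaluate_pipeline(
    truth: GroundTruth,
    config: SimConfig,
    panel: ReferencePanel,
    input_table: AsvTable,
    decision_log: pd.DataFrame,
    site_calls,
) -> dict:
    """Score the pipeline's decisions against the generator's ground truth.

    Returns per-rule confusion summaries (terminal chimeras, batch
    contamination, low-abundance removals) and occupancy recovery from the
    site calls.
    """
    seq_to_asv = {seq: asv for asv, seq in input_table.sequences.items()}
    log = decision_log

    def verdict_of(asv: str, site: str) -> tuple[str, str] | None:
        rows = log[(log["asv_id"] == asv) & (log["site"] == site)]
        if len(rows) == 0:
            return None
        r = rows.iloc[0]
        return str(r["verdict"]), str(r["reason"])

    # terminal chimeras
    expected = terminal_chimera_truth(truth, config, panel)
    chim_tp = chim_fn = 0
    for inner, site in expected:
        asv = seq_to_asv.get(inner)
        if asv is None:
            continue  # no error-free read survived QC; not observable
        v = verdict_of(asv, site)
        if v is not None and v[1] == "CHIMERA_TERMINAL" and v[0] == "remove":
            chim_tp += 1
        else:
            chim_fn += 1
    pure = {
        seq for site in truth.resident_haplotypes
        for seq in truth.resident_haplotypes[site].values()
    }
    chim_fp = int(
        sum(
            1
            for _, r in log[log["reason"] == "CHIMERA_TERMINAL"].iterrows()
            if r["verdict"] == "remove"
            and input_table.sequences.get(r["asv_id"]) in pure
        )
    )

    # batch contamination
    cont_tp = cont_fn = 0
    for ev in truth.contamination_events:
        asv = seq_to_asv.get(ev.asv_sequence)
        if asv is None:
            cont_fn += 1
            continue
        v = verdict_of(asv, ev.target_site)
        if v is not None and v[1] == "CONTAMINATION_BATCH":
            cont_tp += 1
        else:
            cont_fn += 1
    event_targets = {
        (seq_to_asv.get(ev.asv_sequence), ev.target_site)
        for ev in truth.contamination_events
    }
    cont_fp = int(
        sum(
            1
            for _, r in log[log["reason"] == "CONTAMINATION_BATCH"].iterrows()
            if (r["asv_id"], r["site"]) not in event_targets
            and input_table.sequences.get(r["asv_id"])
            in {
                s
                for site in truth.resident_haplotypes
                for s in truth.resident_haplotypes[site].values()
            }
            and r["site"] in truth.resident_haplotypes
            and input_table.sequences[r["asv_id"]]
            in truth.resident_haplotypes[r["site"]].values()
        )
    )

    # low-abundance: removals of detections that are true resident haplotypes
    low = log[log["reason"].isin(
        ["LOW_ABUNDANCE_UNCORROBORATED", "LOW_ABUNDANCE_NEAR_COMMON"]
    )]
    low_removed_true = int(
        sum(
            1
            for _, r in low.iterrows()
            if r["site"] in truth.resident_haplotypes
            and input_table.sequences.get(r["asv_id"])
            in truth.resident_haplotypes[r["site"]].values()
        )
    )

    # occupancy recovery
    occ_truth = {s: (lin is not None) for s, lin in truth.occupancy.items()}
    called = {c.site: c.positive for c in site_calls}
    tp = sum(1 for s, o in occ_truth.items() if o and called.get(s, False))
    fn = sum(1 for s, o in occ_truth.items() if o and not called.get(s, False))
    fp = sum(1 for s, o in occ_truth.items() if not o and called.get(s, False))
    tn = sum(1 for s, o in occ_truth.items() if not o and not called.get(s, False))

    return {
        "terminal_chimeras": _confusion(chim_tp, chim_fn, chim_fp),
        "contamination": _confusion(cont_tp, cont_fn, cont_fp),
        "low_abundance_removed_true_residents": low_removed_true,
        "occupancy": _confusion(tp, fn, fp, tn),
        "n_expected_terminal_chimeras": len(expected),
        "n_contamination_events": len(truth.contamination_events),
    }
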