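"""Site detection calls, haplotype grouping, and survey concordance.

A sample is positive when it retains at least one curated detection (a
single read suffices by default: the assay treats a curated 4-read
detection as a weak positive), and a site is positive when any of its
samples is.  Retained ASVs cluster into haplotype groups by single-linkage
on pairwise p-distance -- single linkage because real groups chain
near-identical haplotypes differing at only a few nucleotide sites -- and
each group is labeled "nr.-<taxon>" after the nearest named reference of
its most abundant member.  Concordance against conventional surveys calls
a site conventionally positive when it has at least one detection within
the comparison window (default 5 years) and reports site concordance and
the sample-level detection rate at conventionally positive sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .align import align_identity
from .asvtable import AsvTable
from .curation import best_reference_hit
from .panel import ReferencePanel

__all__ = [
    "SiteCall",
    "HaplotypeGroup",
    "ConcordanceReport",
    "call_sites",
    "cluster_haplotype_groups",
    "label_groups",
    "concordance",
    "round_pct",
]


@dataclass
class SiteCall:
    site: str
    positive: bool
    supporting_asvs: list[str] = field(default_factory=list)
    total_reads: int = 0


@dataclass
class HaplotypeGroup:
    label: str | None
    members: list[str]
    total_reads: int
    max_divergence: float  # % within-group single-linkage chain


@dataclass
class ConcordanceReport:
    per_site: pd.DataFrame  # site, edna, conventional, agree
    n_compared: int
    n_agree: int
    site_concordance_pct: float
    n_samples_at_positive_sites: int
    n_positive_samples: int
    sample_detection_rate_pct: float
    excluded_sites: list[str] = field(default_factory=list)


def round_pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded half-up to ``decimals`` places."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def call_sites(
    table: AsvTable,
    sites: pd.DataFrame,
    min_reads: int = 1,
) -> tuple[pd.DataFrame, list[SiteCall]]:
    """Per-sample and per-site positivity from a curated table.

    Returns (sample_calls frame with columns sample/site/reads/positive,
    site calls).  ``min_reads`` exists for sensitivity analyses; the
    default treats any retained read as a detection.
    """
    if table.samples is None:
        raise ValueError("sample metadata required")
    unknown = {
        str(table.samples.loc[s, "site"]) for s in table.counts.columns
    } - set(sites.index.astype(str))
    if unknown:
        raise ValueError(f"samples mapped to unknown sites: {sorted(unknown)}")
    sample_rows = []
    for sample in table.counts.columns:
        reads = int(table.counts[sample].sum())
        sample_rows.append(
            {
                "sample": sample,
                "site": str(table.samples.loc[sample, "site"]),
                "reads": reads,
                "positive": reads >= min_reads,
            }
        )
    sample_calls = pd.DataFrame(
        sample_rows, columns=["sample", "site", "reads", "positive"]
    )
    sc = table.site_counts()
    calls = []
    for site in sites.index.astype(str):
        if site in map(str, sc.columns):
            col = sc[site]
            supporting = [a for a in sc.index if col[a] >= min_reads and col[a] > 0]
            total = int(col.sum())
        else:
            supporting, total = [], 0
        calls.append(
            SiteCall(
                site=site,
                positive=len(supporting) > 0,
                supporting_asvs=supporting,
                total_reads=total,
            )
        )
    return sample_calls, calls


def cluster_haplotype_groups(
    table: AsvTable, threshold: float = 0.01
) -> list[HaplotypeGroup]:
    """Single-linkage clusters of retained ASVs at a p-distance threshold.

    ASVs are canonically ordered (total reads descending, then id) before
    clustering, and groups are numbered by descending total reads, so the
    output is invariant to input order.
    """
    if len(table.asv_ids) == 0:
        raise ValueError("no retained ASVs to cluster")
    totals = table.total_counts()
    asvs = sorted(table.asv_ids, key=lambda a: (-int(totals[a]), a))
    parent = {a: a for a in asvs}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(asvs):
        for b in asvs[i + 1:]:
            ident, _ = align_identity(table.sequences[a], table.sequences[b])
            d = 1.0 - ident / 100.0
            dist[(a, b)] = d
            if d <= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra

    members: dict[str, list[str]] = {}
    for a in asvs:
        members.setdefault(find(a), []).append(a)
    groups = []
    for mem in members.values():
        total = int(sum(totals[a] for a in mem))
        max_div = 0.0
        for i, a in enumerate(mem):
            for b in mem[i + 1:]:
                key = (a, b) if (a, b) in dist else (b, a)
                max_div = max(max_div, dist[key])
        groups.append(
            HaplotypeGroup(
                label=None,
                members=mem,
                total_reads=total,
                max_divergence=100.0 * max_div,
            )
        )
    groups.sort(key=lambda g: (-g.total_reads, g.members[0]))
    return groups


def label_groups(
    groups: list[HaplotypeGroup], table: AsvTable, panel: ReferencePanel
) -> list[HaplotypeGroup]:
    """Label each group by its most abundant member's nearest named reference."""
    totals = table.total_counts()
    for g in groups:
        top = max(g.members, key=lambda a: (int(totals[a]), a))
        hit = best_reference_hit(table.sequences[top], panel)
        g.label = f"nr.-{panel.get(hit.ref_id).taxon}"
    return groups


def concordance(
    sample_calls: pd.DataFrame,
    site_calls: list[SiteCall],
    conventional: pd.DataFrame,
    window_years: int = 5,
    as_of_year: int | None = None,
) -> ConcordanceReport:
    """Compare eDNA site calls with conventional survey records.

    ``conventional`` needs columns site/year/detected (boolean or 0/1).  A
    site is conventionally positive iff it has >= 1 detection within the
    ``window_years``-year window ending at ``as_of_year`` (default: the
    latest surveyed year).  Sites present in only one input are excluded
    and listed in the report.
    """
    conv = conventional.copy()
    conv["site"] = conv["site"].astype(str)
    conv["detected"] = conv["detected"].astype(bool)
    if as_of_year is None:
        as_of_year = int(conv["year"].max())
    window = conv[conv["year"] > as_of_year - window_years]
    conv_status = window.groupby("site")["detected"].any()

    edna_status = {c.site: c.positive for c in site_calls}
    shared = sorted(set(conv_status.index) & set(edna_status))
    excluded = sorted(
        (set(conv_status.index) | set(edna_status)) - set(shared)
    )
    rows = []
    for site in shared:
        e, c = bool(edna_status[site]), bool(conv_status[site])
        rows.append({"site": site, "edna": e, "conventional": c, "agree": e == c})
    per_site = pd.DataFrame(rows, columns=["site", "edna", "conventional", "agree"])
    n_compared = len(per_site)
    n_agree = int(per_site["agree"].sum()) if n_compared else 0

    conv_pos = {s for s in shared if conv_status[s]}
    samples = sample_calls[sample_calls["site"].astype(str).isin(conv_pos)]
    n_samples = len(samples)
    n_pos = int(samples["positive"].sum())

    return ConcordanceReport(
        per_site=per_site,
        n_compared=n_compared,
        n_agree=n_agree,
        site_concordance_pct=round_pct(n_agree, n_compared),
        n_samples_at_positive_sites=n_samples,
        n_positive_samples=n_pos,
        sample_detection_rate_pct=round_pct(n_pos, n_samples),
        excluded_sites=[str(s) for s in excluded],
    )
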