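"""ASV curation rules: identity, chimeras, contamination, low abundance."""

import math

import numpy as np
import pandas as pd
import pytest

from pyrgedna.align import align_identity, mismatch_distance
from pyrgedna.asvtable import AsvTable
from pyrgedna.curation import (
    CurationConfig,
    best_reference_hit,
    collapse_reverse_complements,
    apply_low_abundance_rule,
    curate,
    flag_batch_contamination,
    flag_divergent_chimeras,
    flag_terminal_chimeras,
    haversine_miles,
    select_target_asvs,
)
from pyrgedna.iupac import reverse_complement
from pyrgedna.panel import ReferencePanel, ReferenceRecord


def rand_seq(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def dp_semiglobal_score(a, b):
    """Independent oracle for the optimal free-end-gap alignment score.

    Free end gaps mean the alignment may discard, for free, a prefix of
    one sequence and a suffix of one sequence (glocal semantics): the
    first aligned column starts at row 1 or column 1, and the last ends at
    row n or column m.  Internal gaps are affine: open -5 for the first
    gap base, -2 per extension; match 2, mismatch -3 -- mirroring the
    package aligner.
    """
    ga_open, ga_ext = -5.0, -2.0
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    best = NEG
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 2.0 if ai == b[j - 1] else -3.0
            fresh = 0.0 if (i == 1 or j == 1) else NEG
            M[i, j] = s + max(
                fresh, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            )
            X[i, j] = max(M[i - 1, j] + ga_open, X[i - 1, j] + ga_ext)
            Y[i, j] = max(M[i, j - 1] + ga_open, Y[i, j - 1] + ga_ext)
            if (i == n or j == m) and M[i, j] > best:
                best = M[i, j]
    return best


class TestAlignIdentity:
    def test_identical(self):
        s = "A" * 100 + "C" * 100
        assert align_identity(s, s) == (100.0, 200)

    def test_single_substitution(self):
        rng = np.random.default_rng(0)
        a = rand_seq(200, rng)
        b = a[:100] + ("A" if a[100] != "A" else "C") + a[101:]
        ident, cols = align_identity(a, b)
        assert cols == 200
        assert ident == pytest.approx(99.5)

    def test_overhang_excluded_from_columns(self):
        rng = np.random.default_rng(1)
        core = rand_seq(150, rng)
        ident, cols = align_identity(core, rand_seq(30, rng) + core)
        assert ident == 100.0
        assert cols == 150

    def test_reverse_complement_far_below_gate(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rand_seq(250, rng)
            ident, cols = align_identity(x, str(reverse_complement(x)))
            matches = ident * cols / 100.0
            # a revcomp never approaches a near-full-length high-identity hit
            assert matches < 0.75 * len(x)

    def test_score_matches_dp_oracle_on_random_pairs(self):
        # the package aligner and the independent DP must agree on the
        # optimal semi-global score for random related pairs
        from pyrgedna.align import _ALIGNER

        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(30, 120))
            a = rand_seq(n, rng)
            b = list(a)
            for _ in range(int(rng.integers(0, 6))):
                p = int(rng.integers(len(b)))
                b[p] = "ACGT"[rng.integers(4)]
            if rng.random() < 0.5:  # indel
                p = int(rng.integers(1, len(b)))
                del b[p]
            b = "".join(b)
            expected_score = dp_semiglobal_score(a, b)
            got = _ALIGNER.align(a, b)[0].score
            assert got == pytest.approx(expected_score)

    def test_identity_matches_dp_oracle_on_substitution_pairs(self):
        # substitution-only pairs have an unambiguous alignment; matches
        # from the traceback must agree exactly
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(50, 400))
            a = rand_seq(n, rng)
            b = list(a)
            k = int(rng.integers(0, 8))
            for p in rng.choice(n, size=k, replace=False):
                b[p] = "ACGT"[(("ACGT".index(b[p])) + 1 + rng.integers(3)) % 4]
            b = "".join(b)
            ident, cols = align_identity(a, b)
            assert cols == n
            hamming = sum(1 for x, y in zip(a, b) if x != y)
            assert ident == pytest.approx(100.0 * (n - hamming) / n)

    def test_mismatch_distance(self):
        assert mismatch_distance("ACGT", "ACGA") == 1
        assert mismatch_distance("ACGTACGT", "ACGTACGT") == 0


@pytest.fixture
def small_panel():
    # REF_B differs from REF_A at 16 evenly spaced diagnostic sites
    # (positions 10, 30, ..., 310; ~5.1% divergence)
    rng = np.random.default_rng(7)
    a = rand_seq(316, rng)
    b = list(a)
    for p in range(10, 316, 20):
        b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
    return ReferencePanel(
        [
            ReferenceRecord("REF_A", "P. alpha", a, ((40.0, -118.0),)),
            ReferenceRecord("REF_B", "P. beta", "".join(b), ((31.0, -110.0),)),
        ]
    )


def make_table(seq_counts, samples=None):
    """seq_counts: {asv_id: (sequence, {sample: count})}"""
    all_samples = sorted({s for _, c in seq_counts.values() for s in c})
    counts = pd.DataFrame(
        0, index=list(seq_counts), columns=all_samples, dtype=int
    )
    for asv, (_, c) in seq_counts.items():
        for s, n in c.items():
            counts.loc[asv, s] = n
    return AsvTable(
        sequences={a: s for a, (s, _) in seq_counts.items()},
        counts=counts,
        samples=samples,
    )


def sample_meta(mapping):
    """mapping: {sample: (site, batch)}"""
    return pd.DataFrame(
        {
            "sample": list(mapping),
            "site": [v[0] for v in mapping.values()],
            "batch": [v[1] for v in mapping.values()],
        }
    ).set_index("sample")


class TestBestHitAndTargetGate:
    def test_exact_hit(self, small_panel):
        hit = best_reference_hit(small_panel.get("REF_A").sequence, small_panel)
        assert hit.ref_id == "REF_A"
        assert hit.identity == 100.0
        assert hit.orientation == "forward"

    def test_reverse_complement_hits_same_reference(self, small_panel):
        rc = str(reverse_complement(small_panel.get("REF_A").sequence))
        hit = best_reference_hit(rc, small_panel)
        assert hit.ref_id == "REF_A"
        assert hit.identity == 100.0
        assert hit.orientation == "reverse"

    def test_random_sequence_is_non_target(self, small_panel):
        rng = np.random.default_rng(8)
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {
                "ASV_1": (small_panel.get("REF_A").sequence, {"s1": 100}),
                "ASV_2": (rand_seq(316, rng), {"s1": 50}),
            },
            samples=meta,
        )
        targets, decisions = select_target_asvs(
            table, small_panel, CurationConfig()
        )
        assert targets == ["ASV_1"]
        assert decisions[0].reason == "NON_TARGET"

    def test_gate_boundary_is_inclusive(self, small_panel):
        cfg = CurationConfig(min_identity=100.0, min_aligned_length=316)
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (small_panel.get("REF_A").sequence, {"s1": 10})},
            samples=meta,
        )
        targets, _ = select_target_asvs(table, small_panel, cfg)
        assert targets == ["ASV_1"]


class TestRevcompCollapse:
    def test_counts_merge_into_forward_orientation(self, small_panel):
        seq = small_panel.get("REF_A").sequence
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {
                "ASV_1": (seq, {"s1": 5}),
                "ASV_2": (str(reverse_complement(seq)), {"s1": 2}),
            },
            samples=meta,
        )
        out, decisions = collapse_reverse_complements(table, small_panel)
        assert out.asv_ids == ["ASV_1"]
        assert int(out.counts.loc["ASV_1", "s1"]) == 7
        assert decisions[0].reason == "REVCOMP_COLLAPSED"
        hit = best_reference_hit(out.sequences["ASV_1"], small_panel)
        assert hit.orientation == "forward"

    def test_no_pairs_is_identity(self, small_panel):
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (small_panel.get("REF_A").sequence, {"s1": 5})},
            samples=meta,
        )
        out, decisions = collapse_reverse_complements(table, small_panel)
        assert out.counts.equals(table.counts)
        assert decisions == []


class TestTerminalChimeras:
    def test_constructed_3prime_swap_is_flagged(self, small_panel):
        rng = np.random.default_rng(9)
        dom = small_panel.get("REF_A").sequence
        foreign = rand_seq(316, rng)
        chimera = dom[:-60] + foreign[-60:]
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (dom, {"s1": 1000}), "ASV_2": (chimera, {"s1": 30})},
            samples=meta,
        )
        decisions = flag_terminal_chimeras(table, small_panel, CurationConfig())
        assert len(decisions) == 1
        d = decisions[0]
        assert (d.asv_id, d.reason, d.verdict) == (
            "ASV_2", "CHIMERA_TERMINAL", "remove",
        )
        assert "3prime" in d.evidence

    def test_constructed_5prime_swap_is_flagged(self, small_panel):
        rng = np.random.default_rng(10)
        dom = small_panel.get("REF_A").sequence
        chimera = rand_seq(316, rng)[:60] + dom[60:]
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (dom, {"s1": 1000}), "ASV_2": (chimera, {"s1": 30})},
            samples=meta,
        )
        decisions = flag_terminal_chimeras(table, small_panel, CurationConfig())
        assert len(decisions) == 1
        assert "5prime" in decisions[0].evidence

    def test_near_identical_window_not_flagged(self, small_panel):
        # 1-2 bp variants share >90% window identity: not chimeras
        dom = small_panel.get("REF_A").sequence
        variant = dom[:-5] + ("A" if dom[-5] != "A" else "C") + dom[-4:]
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (dom, {"s1": 1000}), "ASV_2": (variant, {"s1": 30})},
            samples=meta,
        )
        assert flag_terminal_chimeras(table, small_panel, CurationConfig()) == []

    def test_parent_itself_never_flagged(self, small_panel):
        dom = small_panel.get("REF_A").sequence
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table({"ASV_1": (dom, {"s1": 1000})}, samples=meta)
        assert flag_terminal_chimeras(table, small_panel, CurationConfig()) == []


class TestDivergentChimeras:
    def test_breakpoint_recovered_within_tolerance(self, small_panel):
        # two-parent recombinant at position 120 between REF_A and REF_B
        a = small_panel.get("REF_A").sequence
        b = small_panel.get("REF_B").sequence
        recombinant = a[:120] + b[120:]
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (a, {"s1": 1000}), "ASV_2": (recombinant, {"s1": 322})},
            samples=meta,
        )
        cfg = CurationConfig(divergent_band=(0.5, 7.0))
        decisions = flag_divergent_chimeras(table, small_panel, cfg)
        assert len(decisions) == 1
        d = decisions[0]
        assert d.verdict == "review"
        assert "REF_B" in d.evidence
        # breakpoint reported within +/-5 bp of the construction point
        reported = int(d.evidence.split("position ")[1].split(" ")[0])
        assert abs(reported - 120) <= 5

    def test_sub_band_divergence_not_a_candidate(self, small_panel):
        a = small_panel.get("REF_A").sequence
        variant = a[:100] + ("A" if a[100] != "A" else "C") + a[101:]
        meta = sample_meta({"s1": ("SITE_1", "B1")})
        table = make_table(
            {"ASV_1": (a, {"s1": 1000}), "ASV_2": (variant, {"s1": 100})},
            samples=meta,
        )
        assert flag_divergent_chimeras(table, small_panel, CurationConfig()) == []


class TestHaversine:
    def test_zero_distance(self):
        assert haversine_miles((40.0, -110.0), (40.0, -110.0)) == 0.0

    def test_antipodal_closed_form(self):
        assert haversine_miles((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
            math.pi * 3958.8, rel=1e-6
        )

    def test_symmetry(self):
        a, b = (39.5, -118.2), (31.5, -110.3)
        assert haversine_miles(a, b) == pytest.approx(haversine_miles(b, a))

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_miles((95.0, 0.0), (0.0, 0.0))


def distant_sites():
    return pd.DataFrame(
        {
            "site": ["NEAR_1", "NEAR_2", "FAR_1"],
            "latitude": [39.5, 39.6, 31.5],
            "longitude": [-118.2, -118.2, -110.3],
            "batch": ["B1", "B2", "B1"],
        }
    ).set_index("site")


class TestBatchContamination:
    def test_same_batch_distant_pair_flagged(self, small_panel):
        seq = small_panel.get("REF_B").sequence  # known near FAR_1's region
        meta = sample_meta(
            {"s1": ("NEAR_1", "B1"), "s3": ("FAR_1", "B1")}
        )
        table = make_table(
            {"ASV_1": (seq, {"s1": 40, "s3": 900})}, samples=meta
        )
        cfg = CurationConfig()
        decisions = flag_batch_contamination(
            table, distant_sites(), small_panel, cfg
        )
        by_site = {d.site: d for d in decisions}
        # FAR_1 sits within 50 miles of REF_B's known locality -> retained;
        # NEAR_1 is ~500+ miles from it -> contamination
        assert by_site["FAR_1"].reason == "RETAINED_CORROBORATED"
        assert by_site["NEAR_1"].reason == "CONTAMINATION_BATCH"
        assert by_site["NEAR_1"].verdict == "remove"

    def test_cross_batch_distant_pair_not_flagged(self, small_panel):
        seq = small_panel.get("REF_B").sequence
        meta = sample_meta(
            {"s2": ("NEAR_2", "B2"), "s3": ("FAR_1", "B1")}
        )
        table = make_table(
            {"ASV_1": (seq, {"s2": 40, "s3": 900})}, samples=meta
        )
        assert (
            flag_batch_contamination(
                table, distant_sites(), small_panel, CurationConfig()
            )
            == []
        )

    def test_same_batch_nearby_pair_not_flagged(self, small_panel):
        seq = small_panel.get("REF_A").sequence
        sites = distant_sites().copy()
        sites.loc["NEAR_2", "batch"] = "B1"
        meta = sample_meta(
            {"s1": ("NEAR_1", "B1"), "s2": ("NEAR_2", "B1")}
        )
        table = make_table(
            {"ASV_1": (seq, {"s1": 40, "s2": 900})}, samples=meta
        )
        assert (
            flag_batch_contamination(
                table, sites, small_panel, CurationConfig()
            )
            == []
        )

    def test_no_locality_data_keeps_strongest_for_review(self):
        rng = np.random.default_rng(11)
        seq = rand_seq(316, rng)
        panel = ReferencePanel([ReferenceRecord("REF_X", "P. x", seq)])
        meta = sample_meta({"s1": ("NEAR_1", "B1"), "s3": ("FAR_1", "B1")})
        table = make_table({"ASV_1": (seq, {"s1": 40, "s3": 900})}, samples=meta)
        decisions = flag_batch_contamination(
            table, distant_sites(), panel, CurationConfig()
        )
        by_site = {d.site: d for d in decisions}
        assert by_site["FAR_1"].verdict == "review"
        assert by_site["NEAR_1"].verdict == "remove"


class TestLowAbundanceRule:
    def test_corroborated_low_read_detection_retained(self, small_panel):
        # mirrors retaining a 39-read detection at 99.65% identity to a
        # reference known from the same area
        ref = small_panel.get("REF_B").sequence
        variant = ref[:200] + ("A" if ref[200] != "A" else "C") + ref[201:]
        ident, _ = align_identity(variant, ref)
        assert ident >= 99.5
        meta = sample_meta({"s3": ("FAR_1", "B1")})
        table = make_table({"ASV_1": (variant, {"s3": 39})}, samples=meta)
        decisions = apply_low_abundance_rule(
            table, small_panel, distant_sites(), CurationConfig()
        )
        assert decisions[0].reason == "RETAINED_CORROBORATED"
        assert decisions[0].verdict == "keep"

    def test_exact_match_15_reads_retained(self, small_panel):
        ref = small_panel.get("REF_B").sequence
        meta = sample_meta({"s3": ("FAR_1", "B1")})
        table = make_table({"ASV_1": (ref, {"s3": 15})}, samples=meta)
        decisions = apply_low_abundance_rule(
            table, small_panel, distant_sites(), CurationConfig()
        )
        assert decisions[0].reason == "RETAINED_CORROBORATED"

    def test_near_common_variant_removed(self, small_panel):
        dom = small_panel.get("REF_A").sequence
        variant = dom[:50] + ("A" if dom[50] != "A" else "C") + dom[51:]
        meta = sample_meta({"s1": ("NEAR_1", "B1")})
        table = make_table(
            {"ASV_1": (dom, {"s1": 10000}), "ASV_2": (variant, {"s1": 30})},
            samples=meta,
        )
        decisions = apply_low_abundance_rule(
            table, small_panel, distant_sites(), CurationConfig()
        )
        assert len(decisions) == 1
        assert decisions[0].reason == "LOW_ABUNDANCE_NEAR_COMMON"

    def test_uncorroborated_low_read_removed(self, small_panel):
        # REF_A's locality is ~500+ miles from FAR_1: no corroboration
        ref = small_panel.get("REF_A").sequence
        meta = sample_meta({"s3": ("FAR_1", "B1")})
        table = make_table({"ASV_1": (ref, {"s3": 39})}, samples=meta)
        decisions = apply_low_abundance_rule(
            table, small_panel, distant_sites(), CurationConfig()
        )
        assert decisions[0].reason == "LOW_ABUNDANCE_UNCORROBORATED"

    def test_threshold_monotonicity(self, small_panel):
        # raising the read threshold never rescues a previously removed
        # uncorroborated detection
        ref = small_panel.get("REF_A").sequence
        meta = sample_meta({"s3": ("FAR_1", "B1")})
        table = make_table({"ASV_1": (ref, {"s3": 39})}, samples=meta)
        lo = apply_low_abundance_rule(
            table, small_panel, distant_sites(), CurationConfig()
        )
        hi = apply_low_abundance_rule(
            table, small_panel, distant_sites(),
            CurationConfig(low_abundance_reads=100),
        )
        removed_lo = {
            (d.asv_id, d.site) for d in lo
            if d.reason == "LOW_ABUNDANCE_UNCORROBORATED"
        }
        removed_hi = {
            (d.asv_id, d.site) for d in hi
            if d.reason == "LOW_ABUNDANCE_UNCORROBORATED"
        }
        assert removed_lo <= removed_hi


class TestCurateComposite:
    def test_empty_table(self, small_panel):
        table = make_table({}, samples=sample_meta({"s1": ("NEAR_1", "B1")}))
        curated, log = curate(table, small_panel, distant_sites())
        assert curated.asv_ids == []
        assert len(log) == 0

    def test_log_is_exhaustive_and_conserved(self, small_panel):
        rng = np.random.default_rng(12)
        dom = small_panel.get("REF_A").sequence
        variant = dom[:90] + ("A" if dom[90] != "A" else "C") + dom[91:]
        meta = sample_meta({"s1": ("NEAR_1", "B1"), "s2": ("NEAR_2", "B2")})
        table = make_table(
            {
                "ASV_1": (dom, {"s1": 900, "s2": 700}),
                "ASV_2": (variant, {"s1": 30}),
                "ASV_3": (rand_seq(316, rng), {"s2": 80}),
            },
            samples=meta,
        )
        curated, log = curate(table, small_panel, distant_sites())
        input_detections = {
            (a, s) for a, s, _ in table.detections()
        }
        assert set(zip(log["asv_id"], log["site"])) == input_detections
        assert len(log) == len(input_detections)
        assert set(log["verdict"]) <= {"keep", "remove", "review"}
        # removals excluded, keeps retained
        assert "ASV_1" in curated.asv_ids
        assert "ASV_2" not in curated.asv_ids  # near-common, 30 reads
        assert "ASV_3" not in curated.asv_ids  # non-target
        assert curated.counts.values.sum() <= table.counts.values.sum()

    def test_determinism(self, small_panel):
        rng = np.random.default_rng(13)
        dom = small_panel.get("REF_A").sequence
        meta = sample_meta({"s1": ("NEAR_1", "B1")})
        table = make_table(
            {
                "ASV_1": (dom, {"s1": 900}),
                "ASV_2": (rand_seq(316, rng), {"s1": 20}),
            },
            samples=meta,
        )
        _, log1 = curate(table, small_panel, distant_sites())
        _, log2 = curate(table, small_panel, distant_sites())
        assert log1.equals(log2)
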