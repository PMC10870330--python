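# Methods

`pyrgedna` implements an eDNA metabarcoding detection-and-discovery
workflow for *Pyrgulopsis* springsnails: degenerate-primer arithmetic and
screening, an exogenous positive control with inhibition calling, amplicon
read QC and merging, a reason-coded ASV curation cascade, haplotype
grouping and survey concordance, and a ground-truthed synthetic-data
generator used to evaluate every decision rule end to end.

## IUPAC algebra

All primer arithmetic is set arithmetic over the 15-letter IUPAC
nucleotide alphabet.  Each symbol denotes a nonempty subset of
{A, C, G, T}; fold-degeneracy is the product of per-position set
cardinalities, and a primer-template mismatch at a position means the
concrete template base lies outside the primer's set — equivalently, the
minimum Hamming distance between the template window and any member of
the primer's expansion pool.  The package's default primer pair (the
degeneracy-reduced BF1/BR2-family COI pair, `ACBGGRTGRACYGTRTAYCC` /
`TCDGGRTGHCCRAARAAYCA`) is 96- and 144-fold degenerate by this
arithmetic.  Templates must be concrete: a degenerate template base is an
input error, not a fuzzy match, because the screening questions the
toolkit answers ("would this hypothetical haplotype amplify?") are posed
against concrete hypothetical sequences.

Degeneracy reduction follows the observed-states rule: each anchor
position is rewritten as the union symbol of the concrete bases observed
at that alignment column in the target group.  Gaps and ambiguity codes
in reference rows are excluded from "observed" — ambiguity there reflects
sequencing uncertainty, not biology, and would inflate degeneracy.  When
the observed set escapes the anchor's set the position is widened with a
warning rather than rejected, since published anchors do not bound the
target group's true diversity.

Amplification-robustness screening enumerates (or, above a configurable
census cap of 10^6, seed-samples) hypothetical priming-site windows at
exact per-site mismatch counts up to 3, re-verifies every emitted window,
and reports transparent features per template: per-site and total
mismatch counts and the number of mismatches within 5 bases of each
primer's 3' end.  No amplification-probability model is fitted; the
report is the feature table a screening decision (human or model) needs.

## Positive control and inhibition calling

The packaged positive control is a 255 bp synthetic amplicon: a
thylacine-derived insert flanked by concrete 20 bp priming sites that are
exact (0-mismatch) expansions of the degenerate primers.  Controls are
built to run a fixed offset (default 100 bp) shorter than the true target
amplicon so the two are separable on an agarose gel, and validated for
(i) 0 mismatches at both priming sites, (ii) the expected length offset,
and (iii) exogeneity — under 75% semi-global identity to every panel
reference, so no control read can be mistaken for a detection.  The
reference amplicon length is a configuration value (default 316 bp, the
conventional scale of this COI fragment), not a constant.

Replicate classification is a total three-state function.  With the
control spiked into exactly one of the (typically four) replicates: a
band near the target length anywhere makes the sample CANDIDATE_POSITIVE;
otherwise no band anywhere (including the spiked replicate) means
INHIBITED; otherwise the sample amplified only the control and is
NEGATIVE_UNINHIBITED.  Band-length tolerance defaults to ±20 bp, an
agarose-resolution figure; it is configurable because gel scoring
precision varies.

## Read processing

QC applies, in order: degenerate-aware primer-prefix trimming (0
mismatches by default; reads without the primer are rejected
`no_primer`), truncation *before* the first base with Q ≤ 4 (the common
denoising convention; the alternative "at" reading differs by one base),
truncation to 250 bp, then rejection for remaining ambiguous bases, more
than 2 expected errors (Σ 10^(−Q/10)), or length under 25 bp.  Each
rejection carries a reason code and per-sample accounting satisfies
reads_in = retained + Σ rejected.

Pairs merge on the longest suffix/prefix overlap (≥ 12 bp, 0 mismatches
by default; longest overlap wins ties, found with a linear-time border
computation).  Merged reads dereplicate into an ASV × sample count table
with ids assigned by descending total count, ties broken lexicographically
by sequence.

Dereplication is a deliberate stand-in for an error-model denoiser, which
is a published external tool and not re-implemented here.  The
consequence — 1–2 bp sequencing-error variants survive as distinct
low-count ASVs — is absorbed downstream by the near-common collapse arm
of the low-abundance rule.  Externally denoised tables can be loaded
directly (`AsvTable.read`) and curated identically.

## Curation cascade

Identity everywhere means: matches / alignment columns (terminal gap
columns excluded) from a semi-global pairwise alignment (match 2,
mismatch −3, gap open −5, extend −2, end gaps free), as a percentage.
Best-reference hits are ranked by matched columns first, then identity,
aligned length, and reference id, trying both orientations; ranking by
raw identity alone would let a trivially short perfect end-overlap
outrank a long, slightly imperfect alignment.

The cascade runs in a fixed order; each (ASV, site) detection receives
exactly one final verdict (keep / remove / review) with a machine-readable
reason:

1. **Target gate** — best hit ≥ 75% identity over ≥ 100 aligned bp
   (inclusive).  The gate replaces a database-size-dependent e-value
   cutoff with explicit thresholds.
2. **Reverse-complement collapse** — an ASV equal to the reverse
   complement of a retained ASV folds its counts into the orientation
   that matches the panel.
3. **Terminal chimeras** — for a candidate x and a strictly more
   abundant same-site, same-length ASV m: x is removed when its core
   (minus a 60 bp terminal window) is *exactly* m's core, the window is
   < 90% identical to m's window positionally, and the window does not
   substantially derive from m's own lineage (its best panel hit must be
   m's reference at gate identity over ≥ 80% of the window to absolve
   it).  Window comparisons are positional because the two windows occupy
   the same region by construction; free-end-gap alignment would let
   unrelated windows slide into short spurious overlaps.
4. **Divergent chimeras** — ASVs 3–7% divergent from their site's most
   abundant ASV get a breakpoint scan: the split maximizing prefix
   matches to the common ASV plus suffix matches to any other reference
   (both arrangements).  Because the optimum is a plateau between the
   diagnostic sites flanking the true junction, the reported breakpoint
   is the plateau midpoint.  The verdict is "review" — such sequences are
   recombinants *or* genuine divergent lineages, and the package records
   the evidence rather than deciding.
5. **Batch contamination** — an identical sequence at sites > 500 miles
   apart whose samples share an amplification batch implicates that
   batch; all its detections in the batch are removed unless the site
   lies within 50 miles of a known locality of the ASV's best-hit
   reference (those keep RETAINED_CORROBORATED).  Distances are
   great-circle miles (Earth radius 3958.8 mi).  With no locality data
   the strongest detection is kept for review and the rest removed.
6. **Low abundance** — detections under 50 reads are removed as likely
   error variants when within 2 bp of a strictly more abundant same-site
   ASV, retained when ≥ 99.5% identical to a reference known within 50
   miles, and otherwise removed as uncorroborated potential false
   positives.

"Review" verdicts are provisional: a later definitive rule may override
one, carrying the review evidence forward in the log.  This matters
because a cross-lineage contaminant is often ~5% divergent from the
resident lineage and would otherwise be shielded by its own review flag.
Rule order is deliberate: collapsing precedes abundance rules so counts
are orientation-complete, and contamination precedes the low-abundance
rule so contaminant reads cannot corroborate themselves.

The 50-mile corroboration radius quantifies "known from this area"; it is
a design choice, not an estimate, and is configurable.  The contamination
rule requires exact full-sequence equality between sites (post-collapse).

## Detection and concordance

A sample is positive with ≥ 1 retained read (a configurable minimum
exists for sensitivity analyses); a site is positive with ≥ 1 positive
sample.  Retained ASVs cluster by single linkage on p-distance at 0.01 —
single linkage because real haplotype groups chain near-identical
variants — and groups are labeled `nr.-<taxon>` by the best hit of their
most abundant member.  Concordance against conventional survey records
calls a site conventionally positive on ≥ 1 detection within a 5-year
window ending at the latest surveyed year, excludes (and lists) sites
present in only one input, and reports site concordance and the
sample-level detection rate at conventionally positive sites, as
percentages rounded half-up to one decimal.

## Synthetic-data generator

The generator emulates the statistical structure the rules assume, with
full per-read provenance:

- **Panel**: 4 lineages at 5% pairwise divergence over a 316 bp amplicon,
  each a mutated copy of a common root confined to the inner region so
  every reference keeps exact expansions of the degenerate primers at its
  ends.  Lineages alternate between two region boxes (Nevada-like and
  Arizona-like centers ~700 miles apart); each lineage's known locality
  is its region box center.
- **Landscape**: sites alternate regions inside 40-mile boxes; batches
  group consecutive site pairs so every batch spans both regions (the
  contamination rule is otherwise unexercisable); occupancy is Bernoulli
  (default 0.5) with the resident lineage drawn from the site's region.
- **Reads**: per occupied, capturing sample the dominant haplotype draws
  a Uniform(0.85, 0.95) share of target reads and minors decay
  geometrically; every sample emits exactly its configured depth (default
  50,000 pairs; scaled-down depths are used in tests, see below).
  Substitution errors are i.i.d. per base per mate (default 0.001);
  qualities are Q38 with occasional Q2 tails to exercise truncation.
  Unoccupied — or occupied but non-capturing (`detection_prob`, default
  0.9) — samples receive only background: random-insert amplicons with
  primer-compatible ends, far below the target gate.
- **Chimeras** (default 0.5% of reads): junctions between the dominant
  haplotype and a same-site background sequence.  Half the junctions are
  drawn inside a 60 bp terminal zone — the artifact class the terminal
  rule targets, consistent with template switching concentrating near
  fragment ends — and half uniformly.
- **Contamination**: events copy a source sample's dominant sequence into
  same-batch samples at sites > 500 miles away, at log-uniform 1–2000
  reads, carved out of the target sample's fixed depth.
- Chimera and contamination reads are emitted error-free: both are
  clonal, already-amplified products, and exact sequence identity is
  precisely the signature the corresponding rules key on.

What the generator does *not* model — PCR amplification bias, indels,
realistic quality correlation, eDNA transport and decay, multi-lineage
sites under default settings — bounds what passing tests show: they
certify the decision rules against the stated abundance, error, chimera
and contamination structure, not against every artifact class of real
MiSeq data.

## Problem sizes and numerical choices

Tests and evaluation runs use desk-scale problem sizes chosen as the
smallest that keep every rule's signal comfortably above sampling noise:
12 sites × 2,000 read pairs for the default curation scenario, 8 sites ×
4,000 pairs for the noiseless end-to-end identity (so minor haplotypes
stay above the 50-read threshold), and 20 landscapes × 20 sites × 200
pairs for detection-rate recovery, which is judged against the binomial
95% sampling band around the configured detection probability.  All
simulations are seeded; identical seeds give byte-identical outputs.
Percentages are rounded half-up via decimal arithmetic.  Degeneracy
expansion refuses pools above 4,096 (configurable); template enumeration
falls back to seeded sampling above 10^6 templates.
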