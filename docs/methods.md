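# Methods

## Scope and data model

vcbench evaluates one call set at a time against a truth (reference) set.
Variants are classed by size: SNV (size 0), indel (1–49 bp insertion or
deletion), SV (≥ 50 bp insertion, deletion or duplication). The 50-bp
boundary is applied uniformly (size ≥ 50 → SV) and is configurable
(`classify_variant(..., sv_min_size=...)`).

`VariantCall.pos` is 1-based and points at the first affected base: the
substituted base (SNV), the anchored base (INS) or the first deleted or
duplicated base (DEL/DUP). All interval arithmetic is 0-based half-open
internally; conversions happen only in the VCF/BED readers and writers.
Genotypes are ignored throughout: the evaluation is genotype-blind, and
multiallelic records are decomposed into one call per ALT.

Duplications are a kind of insertion and many long-read callers emit them as
INS, so `dup_to_ins` converts DUP calls to INS at the first breakpoint before
matching. The converted call keeps a `from_dup` flag because two rules remain
DUP-specific: the size-ratio clause applies to DUP-as-INS matching regardless
of read technology, and the 30–200 bp / 0.8× evidence rules key on the
original call being a duplication.

## Matching

Criteria per class, with the defaults in `MatchParams`:

| class | criterion | tie-break |
|---|---|---|
| SNV | same chrom/pos/alt base | n/a |
| indel | same type; distance ≤ 0.5 × called size (1 bp allowed for 1-bp indels); called/truth size ratio ∈ [0.5, 2.0] | nearest position |
| SV INS | breakpoint distance ≤ 200 bp; size ratio ∈ [0.5, 2.0] for long-read calls and DUP-as-INS | nearest breakpoint |
| SV DEL | reciprocal overlap ≥ 50% of both lengths | largest overlap |

Open choices resolved here: the indel distance is anchored at start
positions; "≥ 50% of the respective length" is read as ≥ 50% of *both*
lengths; remaining ties break deterministically by position then identifier.
Matching is many-to-one — multiple calls may match one truth variant; the
default report counts TP calls, matching the precision/recall definitions
below, and match results record the matched truth identifier so distinct
matched-truth counts are also derivable.

Within-call-set duplicate suppression (`deduplicate`) removes same-type
calls at (nearly) the same position — INS within 50 bp, DEL/DUP at ≥ 50%
reciprocal overlap — whose size ratio lies in [0.67, 1.5], keeping the first
in (chrom, pos, size) order; the operation is idempotent. SNVs are exempt
(they have no size; the ratio rule cannot apply).

## Repeat stratification

STR regions: union of a TRF-based `simpleRepeat` UCSC table and a HipSTR
reference BED, each restricted to tandem-repeat tracts of 20–10,000 bp before
the union. SegDup regions: `genomicSuperDups`, not length-filtered (the
tract-length window is a tandem-repeat notion). Region sets are coalesced
sorted interval lists; union, intersection and total length are exact. A
variant's footprint is its reference span for DEL/DUP and the single
anchored base for SNV/INS (an insertion is a point event at its breakpoint);
1 bp of overlap with an STR interval makes the variant STR, otherwise SegDup
overlap makes it SegDup, else nonrepeat. Touching intervals are merged
during coalescing; total length is unaffected either way. A convention flag
handles BED-like files with 1-based starts.

## Truth-set construction

*Non-redundant merging* appends a candidate variant only when it matches no
existing member under the class-specific matching criterion — the package
deliberately uses one notion of "the same variant" for both evaluation and
redundancy. Candidates are also checked against members appended earlier in
the same merge, so the output is internally non-redundant. Merging sets with
disjoint scale universes (e.g. SVs into an SNV set) is an error.

*Consensus selection* clusters calls across ≥ `min_support` (default 4) call
sets by single linkage: INS link at breakpoint distance ≤ 200 bp, DEL at
≥ 50% reciprocal overlap. Size concordance is not enforced for INS clusters
by default (only the breakpoint criterion defines the cluster), but
`enforce_ins_size_ratio=True` turns it on. A cluster supported by at least
`min_support` *distinct* sets emits one representative: members are sorted
by (size, pos, id) and the lower-median element is taken — deterministic and
invariant to input order. Support counts distinct call sets, not member
calls.

## Sampled re-validation and TP2

Tentative FPs are grouped by region (nonrepeat vs. repeat = STR ∪ SegDup) ×
class (SNV, ins, del, INS, DEL) × indel size range (1–5, 6–50 bp), and up to
n = 50 per group are drawn uniformly without replacement; smaller groups are
taken whole. Each group draws from an RNG substream derived from the global
seed and the group key (CRC-32), so sampling is reproducible and independent
of iteration order.

Automated evidence rules (in `EvidenceParams`; evaluated in order, first
applicable rule decides):

1. ≥ 2 reads whose CIGAR carries a same-type event at the locus satisfying
   the class matching predicate against the call → TP. Insertions within one
   read separated by ≤ 10 bp of reference are summed first, because long-read
   aligners fragment large insertions. SNVs count reads whose aligned base
   equals the call's alternate base.
2. Short-read-derived SV INS whose largest observed read insertion near the
   breakpoint is < 10 bp → FP (sub-10 bp read events are also excluded as
   rule-1 support for such calls).
3. DUP < 100 bp: ≥ 2 reads with a 30–200 bp insertion near the breakpoint →
   TP.
4. DUP > 500 bp: ≥ 2 reads with an insertion > 0.8 × the call size → TP.
   (Reachable when the observation is too large for the rule-1 size ratio.)
5. INS/DUP: ≥ 2 reads 5′-clipped near the first breakpoint and ≥ 2 reads
   3′-clipped near the second (the first again for INS) → TP.
6. Otherwise FP; a locus with no reads is FP with a no-coverage flag.

"Near" is ±200 bp (`breakpoint_window`), consistent with the INS matching
distance. DUP calls between 100 and 500 bp have no special observation rule;
rules 1 and 5 still apply. The ≥-2-reads requirement is applied per read
(each supporting read must individually satisfy the predicate). A BED of
sampled loci ± 200 bp is exported for optional manual review in a genome
browser.

TP2 for a group with N initial tFPs, n sampled and k validated is N·k/n,
with an exact Clopper–Pearson interval on k/n ("binomial test" read as the
exact two-sided interval; the point estimate is carried unrounded). Groups
are summed per class × region, interval endpoints componentwise.

## Metrics

Pr = (TP1+TP2)/Call × 100, Rc = (TP1+TP2)/Ref × 100 and
F = Pr·Rc·2·0.01/(Pr+Rc) — F is the harmonic mean of Pr/100 and Rc/100.
Ref is raised to TP1+TP2 when exceeded, so Rc caps at exactly 100; for a
single evaluated call set this is Ref := max(Ref, TP1+TP2). CI endpoints for
Pr/Rc substitute the TP2 interval endpoints into the same formulas
(including the Ref adjustment); how the sampling uncertainty should be
propagated is genuinely open, and endpoint substitution is the simplest
monotone choice. Size-binned reports use indel bins 1–2 / 3–5 / 6–10 /
11–20 / 21–30 / 31–40 / 41–50 bp and configurable SV bins (default 50–99 /
100–199 / 200–499 / 500–999 / ≥ 1000); empty bins are reported as zero rows.
Per-bin metrics use TP1 only, since tFP sampling operates at the class
level.

## Synthetic fixtures: what they emulate and what they do not

`SimulationConfig` defaults define the study conditions: a 1.5-Mb toy genome
with 2.6% STR content (the human genome-wide STR fraction) and 3% segmental
duplication; 150 SNVs, 120+120 indels (half inside STR tracts, mirroring the
roughly 50% repetitive-region share of real indels), 80 SVs and 10 DUPs;
calls degraded to true precision 0.8 and recall 0.9 with Gaussian
position/size jitter (σ = 8 bp / 8%) truncated to stay inside the matching
tolerance of the source variant; a reference set containing 85% of the
planted truth; depth-10 error-free 3-kb reads. Planted variants are
separated by ≥ 250 bp — beyond every matching and deduplication tolerance —
and false calls are placed at least that far from every planted variant of
any class, so each call's label is unambiguous and the generator's labels
provably agree with the matcher (asserted in the tests). Every generator is
deterministic under the seed, with substreams per stage.

The simulation is deliberately idealized: reads are error-free (an optional
substitution rate exists but is off by default), coverage is uniform, the
sample is effectively haploid, and variants never collide or nest. Passing
tests therefore demonstrate the correctness of the bookkeeping — matching,
stratification, sampling, rule evaluation, estimation — not robustness to
noisy alignments, ambiguous repeat placements or clustered variation, which
real data exhibit and which the no-coverage/fragmented-insertion handling
only partially addresses.

## Replicated recovery experiments

`precision_recall_recovery` checks the estimator end to end: per replicate,
2,000 insertion-indel calls on an abstract coordinate grid (600-bp spacing,
far beyond every tolerance) with true precision p, a reference set of size
round(n_tp/r) of which 80% of the truly-called variants are visible (the
other 20% are hidden truths that become tFPs), 50 sampled tFPs adjudicated
by the generator's labels, and the corrected Pr/Rc with CIs. Coverage is the
fraction of 200 replicates whose 95% CI contains 100·p (resp. 100·r). Recall
is defined against the reference-set denominator — the same denominator the
estimator uses; sizing the known set as n_tp/r makes that target exactly r.
Label-based adjudication isolates the uncertainty the CI quantifies (the
50-variant sample); the alignment-evidence rules are validated separately on
simulated reads. Observed coverage is 96–99% across p ∈ {0.6, 0.8, 0.95} ×
r ∈ {0.5, 0.9}: slightly conservative, as expected when a binomial interval
is applied to without-replacement sampling from a finite tFP pool.

## Numerical and engineering choices

Truth lookup uses per-(chrom, class, scale) position-sorted arrays with
bisection; the DEL candidate window is bounded by size/rec_overlap, which is
exhaustive because a truth DEL larger than call/ρ cannot reach ρ reciprocal
overlap. The matcher is checked call-for-call against a quadratic all-pairs
oracle. Alignment evidence fetches via the index when one exists and
otherwise loads the (toy-scale) SAM into per-chromosome sorted lists.
Degenerate inputs: empty call sets yield all-zero metrics with a warning;
an empty sample yields TP2 = 0 with a vacuous [0, 1] interval; review-BED
coordinates clip at zero; symbolic ALTs without a resolvable size are
skipped with a logged warning, falling back from SVLEN to END−POS for
DEL/DUP.

Problem sizes in the test suite and acceptance script (toy genomes ≤ 1.5 Mb,
100 matcher-oracle instances of ≤ 1,000 calls, 6 × 200 recovery replicates,
a 500-SV consensus panel) were chosen so the whole suite completes in about
half a minute while every rule and threshold is exercised on both sides.

## Known limitations

No haplotype- or sequence-level comparison (a matched INS may have a
different inserted sequence); inversions and translocations are out of
scope; genome-build conversion is out of scope; genotype concordance is not
assessed; the evidence rules are threshold-based and quality-unaware; recall
against an incomplete reference remains denominator-biased — the TP2
correction fixes the numerator only, which is why reported recall saturates
when the reference undercounts.
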