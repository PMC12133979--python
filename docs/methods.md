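# Methods

This note documents the models, parameter choices and numerical
conventions behind `gbtspanel`, and what the synthetic studies do and do
not establish about real capture-sequencing data.

## Data model

Genotypes are biallelic diploid calls coded 0/1/2 (alternate-allele
dosage) with −1 for missing; multi-allelic VCF records are rejected
rather than split, because every downstream statistic (MAF, PIC, He)
assumes a fixed per-site allele set and splitting would silently change
allele frequencies.  Positions are 1-based internally; BED output is
0-based half-open.  Depth matrices carry per-(sample, region) read
counts plus per-sample totals (total / on-target / duplicate reads) with
the obvious ordering invariants enforced at construction.  InDels are
carried through I/O and trait calling but excluded from background SNP
statistics — in this workflow they occur only among trait markers.

## Capture QC

Uniformity_X for a sample is the fraction of target regions whose depth
reaches X% of **that sample's own** mean region depth; the cohort value
is the unweighted mean over samples.  A pooled-mean variant would differ
only when samples have very different sequencing yields; the per-sample
form matches how per-run QC is conventionally reported.  A sample with
an all-zero depth row has no defined mean; its uniformity is reported as
0 with a warning.

The on-target rate is on_target_reads / total_reads.  The effective data
rate removes duplicates apportioned to the on-target share:
(on − r·on)/total with r the sample's overall duplication rate.
Duplication is consumed as input metadata — computing it needs
read-level data, which is upstream of this package.

Sequencing at a nominal depth is simulated by independent binomial
thinning: every cell is thinned with p = nominal / cohort-mean depth
(capped at 1), and the on-target surplus, off-target reads and
duplicates are thinned at the same p, so all totals invariants are
preserved, zero cells stay zero and no cell ever increases.  The
expected new cohort mean is min(nominal, old mean).

## Site selection

The three per-site filters are applied with strict inequalities exactly
as published (missing rate < 0.1, uniformity > 0.25, target rate > 0.5,
at 40X).  Site-level "uniformity" and "target rate" are not given
operational definitions in the protocol text; here site uniformity is
the fraction of samples whose depth at the site reaches 25% of the
cohort mean region depth, by analogy with the panel-level definition,
and target rate is the fraction of samples with ≥ 1 read at the site
after 40X thinning.  Both thresholds are configurable.  Sites with no
calls at all have undefined MAF and are discarded with reason
`no_calls`.  Trait-specific sites bypass the filter entirely.

## Panel optimization

The published procedure states five criteria but no algorithm.  A
two-phase greedy is used: gaps first (criterion 2 is a hard spatial
constraint), then MAF shares (criteria 4–5 are set shares that any
high-MAF insertion helps).  Because the mean adjacent gap of a
chromosome telescopes to (last − first)/(k − 1), every pool site strictly
inside the current span gives the same maximal reduction; ties are broken
by larger MAF, then smaller position, making the procedure deterministic.
Phase B inserts the highest-MAF pool site (ties: smaller chromosome,
then position) and stops early if the only unmet share is the top MAF
class and no remaining pool site exceeds 0.4 — further insertion could
only dilute it.

The reinsertion budget is the largest integer strictly below 1% of the
selected background (when 1% is itself an integer, one less than it),
honouring the "strictly fewer than 1%" reading.  The "highest MAF
threshold class" is MAF > 0.4.  Criterion 4's denominator is the
background set (selected + reinserted); criterion 5's is the total panel
including trait sites.  Infeasibility is a reported outcome: the
constraint report carries a satisfied flag per criterion and the audit
trail records every insertion with the metric before and after.  The
published panel's own numbers are not jointly consistent with the budget
criterion, which is precisely why violations are surfaced rather than
forced.

## Diversity statistics

PIC is evaluated exactly as printed, PIC = 1 − Σpᵢ² − Σᵢ<ⱼ2pᵢ²pⱼ², using
the algebraic identity Σᵢ<ⱼ2qᵢqⱼ = (Σq)² − Σq² with q = p²; a brute-force
double loop over allele pairs serves as the test oracle (agreement to
1e−12, spectra up to 6 alleles).  Ae = 1/Σp² and He = 1 − Σp² (Nei) are
the standard definitions; the source protocol names but does not define
them.  Frequencies are always computed over non-missing calls.  The
printed PIC category ranges leave gaps at 0.10 and (0.25, 0.30); the
implementation uses the half-open intervals low [0, 0.10],
medium (0.10, 0.25], high (0.25, 0.40], very high (0.40, 0.50], which
assigns 0.10 to low and the (0.25, 0.30) gap to high.  Marker-set
summaries use the population SD (divisor N).  MAF class bins are
[0, 0.05], (0.05, 0.1], (0.1, 0.2], (0.2, 0.3], (0.3, 0.4], (0.4, 0.5];
the 0.05 boundary belongs to the lowest class, matching the "MAF ≤ 0.05"
column convention of attribution tables.

## Trait-marker calling

Per-site states R/H/S/M (homozygous resistant / heterozygous /
homozygous susceptible / missing) combine into a gene status by a fixed
lattice: any missing site voids the call (`no_call`), otherwise one
homozygous-susceptible site is decisive, otherwise any heterozygous site
gives `heterozygous`, else `resistant`.  The rule is a total,
order-invariant function over {R,H,S,M}^k, verified exhaustively against
an independently coded truth table for k ≤ 5.  The underlying protocol
does not specify how partial haplotype matches resolve; this policy is a
package decision and is kept in one function (`combine_states`) so
alternatives can be swapped in.  Inter-laboratory concordance per gene
excludes pairs where either side is `no_call`, and a gene is confirmed
at agreement ≥ 0.90.  The real resistant/susceptible allele definitions
of commercial panels are proprietary; the package ships the schema and
synthetic fixtures only.

## Probe design

"Homology number" is operationalized as the exact full-length occurrence
count of the probe or its reverse complement across the reference
(overlaps counted; the probe's own locus scores 1).  The original filter
is most likely alignment-based on the full genome; exact matching keeps
the filter deterministic and oracle-verifiable while preserving the
threshold semantics (< 3 background, < 5 trait).  Candidate 110 bp
windows are tiled at a 10 bp stride over all placements containing the
site; GC bounds are inclusive at 0.30 and 0.70; survivors are ranked by
|GC − 0.5| then start coordinate.  Near-identical (mismatched) hits and
thermodynamic scoring (Tm, hairpins) are out of scope.

## Synthetic data generator

The generator defines the study conditions used throughout the tests:

* 12 chromosomes with the SL2.40 tomato lengths, scaled by 1/100 by
  default so desk-scale positions stay small while gap statistics behave
  identically (gaps scale linearly).
* Four source databases with their published candidate counts (8,744 /
  680 / 1,248 / 1,552).  Each database draws true alternate-allele
  frequencies from a Beta law whose parameters were calibrated once, via
  the Beta CDF, so the expected MAF > 0.05 share matches the
  corresponding real source (≈ 68%, 54%, 90%, 1.4%): Beta(0.46, 1.5),
  Beta(0.31, 1.5), Beta(0.92, 1.3), Beta(0.009, 3.0).
* Genotypes are Hardy–Weinberg draws from the true frequency with
  independent per-call missingness (default 1%, consistent with a ~99%
  detection rate).  An optional founder-mixture mode adds
  half-sibling-like relatedness for qualitative demonstrations only; the
  calibration properties hold only in the HWE mode.
* Depths are Poisson around log-normal per-region capture multipliers:
  mean depth 100 (the assay's design depth), σ = 0.7 (giving a
  uniformity_50 near the mid-70s%, as observed for a first-pass panel),
  off-target fraction 0.30 and duplicate fraction 0.05.
* Trait-marker truth planting generates genotypes consistent with a
  known per-sample status so the caller can be closed-loop tested; the
  reference allele plays the susceptible role at every site.
* The optimizer fixture builds a deliberately feasible problem: 2,000
  selected sites on 12 scaled chromosomes, eleven of them already inside
  the gap ceiling, one sparse chromosome slightly above it with pool
  sites available in its span, and MAF spectra already meeting the share
  floors — so a correct optimizer must finish with every criterion
  satisfied inside the < 1% budget.

What passing on synthetic data shows: the statistics, filters and
optimizer implement their definitions correctly, are deterministic under
a seed, and are calibrated (empirical rates within 3 standard errors of
their generating parameters).  What it does not show: behaviour under
real capture chemistry — GC-dependent dropout, correlated missingness,
batch effects, population structure and linkage are all absent from the
generator, so real-data QC values (e.g. the published uniformity and
on-target rates) are emulated in distribution, not reproduced.

## Problem sizes and determinism

Default desk-scale runs use the full 12,224-site candidate set with
50–136 samples; calibration tests use up to 2,000 samples at a handful
of sites, and the PIC oracle runs 10,000 random spectra.  All randomness
flows through `numpy.random.Generator` seeds; identical spec + seed give
byte-identical pipeline bundles (run logs contain no timestamps).

## Known limitations

* Exact-match homology understates the true multi-mapping risk of a
  probe on a real genome (no mismatches, no indels).
* The site-level uniformity/target-rate definitions are one reasonable
  reading of an underspecified protocol; both are configurable.
* The greedy optimizer is not optimal — it makes no attempt at ILP/DP
  panel selection and can stall on adversarial pools (reported, not
  hidden).
* Table-style summaries round at the report layer only; all internal
  computation is at full double precision.
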