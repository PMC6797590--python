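# Methods

This package analyzes whether CRISPR-Cas9 editing inflates the de novo
mutation burden in a multigeneration cohort sequenced by whole-exome
capture: a founding pair, a clutch of F0 embryos split across injection
arms (uninjected, Cas9-only, sgRNA-only, edited across six guides at three
loci), and an F1 generation bred from adults of the high-efficiency-guide
arm.  It implements the variant-level analysis only; read processing and
variant calling are upstream and are replaced here by pseudo-caller
simulation with known ground truth.

## The filter cascade (`denovo_filter`)

Candidate de novo variants are raw offspring calls surviving, in order:

1. **Parental exclusion** — any key with call support in either parent.
2. **Known-variant exclusion** — alleles present in a dbSNP-like catalogue
   of wild-type strain variation (guards against parental alleles missed by
   incomplete parental coverage).  Allele-aware: position *and* allele must
   match.  Can be disabled (`use_dbsnp=False`) for the re-analysis mode
   that asks whether this filter discards real edits.
3. **On-target exclusion** — calls within the guide cut loci ± 50 bp
   (expected edits, not collateral damage).  The flank width is a package
   choice; no established value exists.
4. **Region exclusion** — repeat tracts and predicted segmental
   duplications, where mismapping mimics variation.
5. **Repeat-context indel filter** — an indel is removed iff its
   inserted/deleted sequence is a whole number of copies of a unit of
   length ≤ 3 (homo-/di-/trinucleotide) and the flanking reference carries
   ≥ 3 tandem copies of that unit.  SNVs always pass; missing reference
   context fails open with a warning.
6. **Cross-noise removal** — keys called in ≥ 2 distinct samples, which at
   this cohort size are overwhelmingly systematic error or uncalled
   parental mosaicism rather than independent de novo events.  Judged on
   key multiplicity only (never AF or caller).  Scope is cohort-wide by
   default; a `within_guide` scope exists because true off-target edits
   would recur specifically among siblings sharing a guide.
7. **Allele-frequency threshold** — AF ≥ 0.3 captures fixed heterozygous
   variants (inclusive, so AF = 0.30 survives); 0.1 and "none" probe lower
   mosaicism at the cost of caller sensitivity.
8. **Dual-caller intersection** (optional, default on) — (sample, key)
   pairs reported by both callers; AF/depth are reported from the
   designated primary caller.
9. **Suspect flagging** — calls within 25 bp of a parental indel are marked
   `suspect=True`, a rule-based stand-in for manual alignment review.
   Flagged calls are never silently removed; counts are reported with and
   without them ("predicted" vs "reviewed" panels).

Design choices: the first stages are pure set subtractions and commute;
their order is fixed for reporting stability.  Cross-noise runs after the
region filters so recurring repeat artifacts do not consume the ≥ 2-sample
budget.  The per-stage report (`FilterReport`) enforces that every stage's
survivors are a subset of its input.

Variant identity everywhere is the left-normalized `(chrom, pos, ref, alt)`
tuple: alleles are trimmed (trailing then leading shared bases) and indels
shifted to the leftmost position at which the same allele strings produce
an identical haplotype.  This is how two callers' representations of the
same indel are reconciled; position-only matching is rejected because it
would conflate distinct alleles.  Coordinates are 0-based half-open
internally, converted only at VCF boundaries.

## Burden statistics (`burden_stats`)

Per-sample candidate counts are compared between arms with a two-sided
Wilcoxon rank-sum test (two groups; exact enumeration when the combined n
is ≤ 20 and tie-free, otherwise normal approximation with midrank tie
correction) or a Kruskal-Wallis rank test (> 2 groups, chi-square
approximation with tie correction).  Nonparametric tests are the right
choice for small integer counts with no distributional commitment.

Significance is assessed against a Bonferroni critical value of
`alpha_family / n_groups`; report strings show the threshold truncated to
three decimals (0.05/4 = 0.0125 → "0.012").  Dividing by the number of
*groups* (rather than the number of pairwise comparisons) follows the
source analysis's wording; the more conventional pairwise divisor would be
stricter, and the discrepancy is deliberately surfaced here rather than
resolved.  Note 0.05/3 ≈ 0.0167 displays as "0.016", not "0.012" — a
three-group analysis quoting "0.012" is consistent only with a four-way
correction.

## The off-target model (`offtarget_model`)

Pre-cascade calls (the callers are trio-aware, so parental-supported keys
are excluded as they would be at calling time) are intersected with
predicted off-target sites expanded by 100 bp on both sides; overlapping
windows are merged and clipped to the capture space.

Each window hit is triaged by the first matching rule, mirroring manual
review: (1) key carried by a sample of a different guide or a control
condition → `shared_across_conditions`; (2) alt reads on one strand only →
`single_strand` (abstains when strand counts are unknown); (3) carrier is
itself a control → `control_only`; (4) AF below 0.06, near the callers'
limit of detection → `low_af_limit`; (5) absent from the second caller →
`caller_unconfirmed`; otherwise `candidate`.

The chance expectation treats every captured base as a trial: a position
becomes a spurious variant when sequencing error yields at least
`max(min_alt_reads, floor(min_af·depth)+1)` alternate reads — an exact
binomial tail `P(X ≥ t)`, `X ~ Binomial(depth, e)`.  At depth 76 the
"≥ 4 reads" and "AF > 0.05" rules coincide at t = 4.  Scaling by the
capture size N gives the expected chance-variant count K (≈ 2.8 × 10³ at
N = 74,691,693 bp and e = 0.24%).  Observing k distinct hit positions in
n window bp is scored with a hypergeometric upper tail
`P(X ≥ k), X ~ Hypergeom(N, K, n)`.  Distinct positions (not per-sample
calls) are counted so one systematic site cannot inflate enrichment.  Both
platform error scenarios (0.24% and 0.1%) are always reported side by
side as a high/low bracket, and the test is run pooled and per sample.
The N/K/n/k mapping (population = capture bp, successes = expected chance
positions, sample = merged window bp) is the package's interpretation; it
is the only mapping consistent with using the capture space as the
population.  `window_bp = 0` yields an explicitly undefined result, and
k > min(n, K) returns p = 0 with a warning.

## The cohort simulator (`cohortsim`)

The simulator generates the study conditions with known truth so every
downstream stage is testable without sequencing data.

* **Reference and regions**: per-chromosome uniform-base sequences (default
  4 chromosomes, 1 Mb total — a scaled-down stand-in for the 74.7 Mb
  capture; the full size is a config value).  Repeat and segdup tracts are
  planted so the region filters have non-trivial work.
* **Founders**: two diploid parents with heterozygous sites at density
  10⁻³/bp (15% small indels, 70% of those deletions — the substrate for
  alignment artifacts).  A dbSNP-like catalogue holds 90% of founder
  alleles plus extra population alleles at 2 × 10⁻⁴/bp.
* **Transmission**: fair Bernoulli per heterozygous founder allele.  F1
  samples inherit through unsequenced F0 breeding adults of the matching
  condition.  De novo events are Poisson(2.5) per offspring exome (the
  expected 2–3 exonic changes per generation from the ~0.01% per-gene
  per-generation baseline), placed uniformly in the capture: heterozygous
  (AF 0.5) in F1, mosaic in F0 (Beta(2,5) truncated at 0.05).  Events are
  assigned to the generation in which they are counted; separately
  transmitting F0-germline de novo events to F1 is deliberately not
  modelled, since the analysis measures per-generation accrual against the
  same baseline.
* **Editing**: edited F0 carry an on-target allelic series (1–3 deletion
  alleles at the cut site) with mosaic AFs drawn from a truncated Beta —
  mode near 0.5 for high-efficiency guides (Beta(6,4)), long low-AF tail
  for low-efficiency (Beta(1.5,5), edit probability 0.3).  The study
  reports only qualitative efficiency (100% vs ~30%); the Beta shapes are
  a modelling choice, not an inference.  Edited F1 carry one fixed
  heterozygous transmitted on-target allele.  True off-target edits arise
  at rate `offtarget_rate` (default 0 — the null) at the listed predicted
  sites.
* **Pseudo-callers**: two profiles, a strict "germline" caller (effective
  error 0.1%, minimum coverage 30×) and a permissive "somatic" caller
  (0.24%, 10×).  Depth is negative-binomial around 76× (parents/F0) or
  115× (F1), dispersion 50; a non-positive dispersion gives constant depth
  for calibration work.  True variants are detected from binomial read
  sampling against the caller's thresholds, with an extra sensitivity
  decay below AF 0.10.  False positives: (a) per-base binomial sequencing
  error, simulated site-by-site, honestly reproducing the chance-variant
  tail; (b) two indel-adjacent artifact classes near founder deletions —
  gap-fill (spurious SNVs, 2.0/sample) and misrealignment (shifted
  non-equivalent deletions, 0.24/sample), an ~83:10 call ratio; (c)
  systematic cross-noise sites drawn once per simulation and emitted in
  ≥ 2 samples by *both* callers (independent depth draws).
* **Determinism**: all randomness flows from one seed through named
  substreams (reference, founders, per-sample offspring, per-caller
  calls), so a fixed seed reproduces the fixture bundle byte-for-byte and
  stages can be regenerated in isolation.

What the simulator does *not* emulate: read-level alignment, sequence-
context-realistic genomes, linkage between founder sites, caller-specific
genotype likelihood behaviour, or structural variants at the on-target
locus.  Passing tests therefore demonstrate the correctness and
calibration of the *analysis* under the stated generative model, not the
end-to-end error profile of a real exome experiment.

## Numerical choices and degenerate inputs

* Binomial and hypergeometric tails use scipy's survival functions
  (log-space internally; stable for N up to ~10⁸); tests verify them
  against exact rational enumeration and direct pmf summation.
* Ti/Tv over zero transversions returns an explicit undefined value (None),
  never an exception.  The simulator's substitution spectrum carries a
  configurable transition bias (default Ti:Tv 1.2, the ratio reported for
  zebrafish).
* Kruskal-Wallis on all-identical values returns H = 0, p = 1 (scipy
  rejects this case).
* AF thresholds are inclusive; the "AF > 0.05" chance-model rule is strict.
* A group with fewer than two samples is computed with a warning
  (exactness degraded), not refused.
* Missing reference context in the repeat-context filter fails open.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at a 1 Mb
(or smaller) capture stand-in with the study's cohort structure (70
samples) or its F1-only subset (18 samples), 500 replicates for test
calibration, and 60 replicates for the enrichment null — sizes chosen so
the whole analysis reruns in minutes on a single core while keeping every
rate and threshold at its study value.

## Known limitations

* The per-generation burden baseline and the artifact class proportions are
  taken as fixed study conditions, not re-estimated.
* The enrichment model brackets platform error with two fixed rates rather
  than estimating a site-specific error profile.
* Cross-noise removal cannot distinguish systematic error from a true
  recurrent edit shared by ≥ 2 siblings of the same guide at cohort scope;
  the `within_guide` scope and the dbSNP-free re-analysis mode exist to
  probe exactly that, mirroring the source analysis.
* CLI `filter`/`burden`/`offtarget` subcommands exchange JSON rather than a
  database; very large cohorts would want a columnar format.
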