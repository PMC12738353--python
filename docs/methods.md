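# Methods

## The isomiR model

Only templated terminal variants are modelled: an isomiR is a slice of the
precursor hairpin, identified by the mature miRNA name plus signed 5'/3'
offsets from the archetype termini (1-based inclusive hairpin coordinates,
matching the miRBase GFF convention). Positive offsets point toward the
precursor 3' end. Reconstruction is therefore exact — the sequence of
`m o5|o3` is `precursor[start+o5 .. end+o3]` — and reads implying
non-templated nucleotides are rejected loudly rather than mis-sequenced.
Internal edits (polymorphic isomiRs) and multi-mapping across precursors are
out of scope.

The shipped miR-455 hairpin is a synthetic stand-in assembled around the
authentic mature hsa-miR-455-5p arm (`UAUGUGCCUUUGGACUACAUCG`) with the +1
templated U that the published 0|1 probe implies; its flanks and 3p arm are
constructed, so only mature-arm-relative coordinates on it are meaningful.

## Diversity statistics

* **Abundance filter**: strictly more than `min_reads` (default 100) raw
  reads in at least `min_samples` (default 1) samples, applied globally over
  the whole cohort. Per-tissue filtering can be had by subsetting the sample
  columns before filtering; the global form is the default because the
  downstream tissue comparison should see one common isomiR universe.
* **Diversity**: the count of isomiRs with ≥ `presence_min` (default 1)
  reads in a sample, after the global filter. No per-sample abundance rule
  beyond presence is imposed.
* **Eligibility**: across-sample median isoform count ≥ 3 (boundary
  inclusive).
* **Pooled categories**: per tissue, a miRNA's pooled diversity is the union
  of isomiRs seen in any sample of the tissue; the bands {1}, {2–9}, {≥10}
  are exhaustive over positive counts, so the three categories always
  partition the tallied miRNAs. miRNAs unobserved in a tissue are not
  tallied there. Categories empty in both groups are dropped before the χ²
  test (they carry no information and would zero an expected count).
* **More/less split**: above the median → "more", below → "less"; ties at
  the median go to "less" by default (configurable). This is conservative
  for a protective-diversity interpretation: borderline samples are assigned
  to the at-risk group.
* **Two-group test**: Welch's unequal-variance *t*-test by default; the
  pooled-variance flavor is exposed via `equal_var=True`. Two identical
  constant groups are assigned p = 1 by convention (no evidence, no
  division by zero). Raw p-value thresholds are the default (α = 0.01
  tumor/normal, α = 0.05 histology); no multiplicity correction is applied
  because the selection rule is a fixed intersection-plus-fold-change
  filter, not an FDR-controlled discovery list.
* **Fold-change band**: candidates must be significant *and* have
  FC > 2 or FC < ½ (strict), with FC oriented tumor/normal or
  unfavorable/favorable; the band is two-sided because diversity losses in
  the tumor direction are the expected signal.

## Survival

Estimation is delegated to lifelines: Kaplan–Meier product-limit curves,
the multivariate log-rank χ², and Cox partial likelihood with Efron tie
handling (the least-biased common default; the data are day-resolution, so
ties occur). Categorical covariates are one-hot encoded against the first
sorted level, so `diversity_group` enters as `diversity_group_more` (HR < 1
when diversity is protective) and `histology` as `histology_unfavorable`.
The test suite pins the contract independently of the library: a hand
product-limit recomputation, an observed-minus-expected log-rank oracle, and
a grid/scalar maximization of the partial likelihood all agree with the
module to tight tolerances, and parameter-recovery simulations bound the
log-HR bias below 10% at n = 500 over 50 replicates for HR ∈ {0.5, 1, 2}.
Expression ("high/low") splits use the same median rule as the diversity
split. Follow-up can be administratively truncated at a horizon (e.g.
5 × 365 days) to study fixed-horizon event-free survival; by default no
truncation is applied.

## Target scanning

The seed is miRNA positions 2–8 (the 7-mer convention of RNA22-class
tools). A site is a UTR sense-strand window whose reverse complement matches
the seed with at most `max_mismatch` (default 1) mismatches; G:U wobble
counts as a mismatch inside the seed. Scanning is sense-strand only, UTR
input may be DNA or RNA (normalized to RNA), positions are 1-based, and
overlapping hits are all reported.

Each hit also receives an extended-duplex score over the full miRNA length
(antiparallel, Watson–Crick +1, wobble +0.5, else 0; positions running off
the UTR score 0). This is a complementarity count, not a thermodynamic
model — no folding energies are computed. It exists because a pure 3'
extension such as a 0|1 isoform leaves the seed — hence the raw hit list —
unchanged; any archetype-vs-isoform difference in site counts must come from
3'-supplementary pairing, and `compare_site_counts` reports both the raw
seed counts and the "effective" counts above a relative score threshold so
both readings are visible. An empirical null for that threshold is provided
by dinucleotide-preserving UTR shuffles (Altschul–Erikson Eulerian-path
shuffle, written in-house since no installed package exposes one; it
preserves first/last base and every dinucleotide count exactly, which the
tests verify). Candidate gene lists are supplied by the user as UTR FASTA;
no target-prediction database client is included.

## IHC scores

IRS = intensity ordinal (0–3) × proportion bin (0–4) with bins 0%, 1–25%,
26–50%, 51–75%, 76–100%; fractional percentages round half-up to integers
before binning since the bins are integer-valued. The H-score uses the
standard Σ intensity × percent definition (0–300). Two raters' tables are
merged with an exact-agreement report; discordant ordinals are flagged and
resolved by a configurable rule (consensus-required by default, never a
silent average). Group comparisons use Welch's *t* for two groups and
one-way ANOVA for more.

## The synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, at desk
scale, from a single seeded `numpy` generator (same config + seed ⇒
byte-identical outputs):

* **Cohort frame**: `n_tumor` = 127 and `n_normal` = 5 by default, matching
  the analyzed cohort; tumors are unfavorable with probability 0.35 (the
  cohort's histology mix is not published; this sits between typical
  favorable-majority registry rates and the validation cohort's 60%).
* **Isoform counts**: per miRNA and sample, a zero-truncated Poisson draw
  (the simplest positive count model with a controllable mean; the rate is
  inverted from the target mean by root finding). Background miRNAs span
  means 2.5–6 shared across groups. The `n_signal` planted miRNAs start at
  mean 8 in normals and are scaled so that both the tumor/normal and the
  unfavorable/favorable mean ratios equal `diversity_fc` exactly
  (default 3 — a planted effect clearly beyond the 2-fold selection
  threshold, as the reported candidates were; planting exactly at the strict
  threshold would make recovery a coin flip by construction).
* **Reads**: isoforms are ranked by a geometric abundance decay (0.7), with
  the 3'+1 isoform outranking the archetype by default; the present
  isoforms are the top-k of a fixed 16-member offset catalogue whose 5'
  offsets concentrate at 0 and 3' offsets disperse. Reads are negative
  binomial (variance μ + 0.1 μ²) with per-sample depths drawn around
  8.9 M ± 0.7 M and expected sample totals normalized to the drawn depth.
  Signal miRNAs are additionally 2-fold more abundant in tumors, so
  diversity and abundance effects point the way the cohort's did.
* **Survival**: exponential by default (closed form, easy recovery checks;
  Weibull optional) with baseline median 2000 days and log-hazard
  log(hr_diversity)·[less] + log(hr_histology)·[unfavorable]; censoring is a
  Bernoulli(censor_rate) coin with the censoring time uniform before the
  event, so `censor_rate=0` yields all events and the realized censoring
  fraction matches the rate in expectation.
* **Sequences**: random 70-nt hairpins with the mature arm at positions
  9–30; per miRNA one UTR with a manifest-recorded number of exact and
  one-mismatch seed sites, assembled into site-free background and
  re-verified by brute force (so the manifest is ground truth by
  construction). `plant_site_comparison_utr` builds the archetype-vs-isoform
  demonstration UTR: n shared perfect sites plus sites where two non-seed
  archetype pairings are broken while the isoform's 3' extension still
  pairs, together with the relative score threshold that separates the two —
  yielding the 5-vs-4 effective-site pattern with identical seed hits.

What the generator does **not** emulate: read-level artifacts (adapters,
sequencing error), non-templated additions, per-miRNA dispersion structure,
correlated miRNA expression, competing risks, or informative censoring.
Passing tests therefore demonstrate that the estimators and the selection
funnel behave correctly under the assumed generative structure — not that
any particular cohort-specific hit list would be reproduced on real data.

## Problem sizes and tolerances

Calibration tests and the acceptance script use 60 + 60 samples and 20–2000
miRNAs: large enough that planted 3-fold diversity signals are recovered in
every one of 20 held-out seeds and the null false-positive rate at α = 0.01
sits inside its binomial 99% band over 2000 miRNAs, small enough to run in
seconds. Oracle equalities are asserted at 1e-12 (closed forms), 1e-10
(ANOVA/χ² decompositions) and 1e-4 (partial-likelihood maximizer); simulation
recoveries use the bounds stated above. Degenerate inputs (all-equal splits,
zero-variance groups, empty categories, all-censored samples) are handled
explicitly and tested.
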