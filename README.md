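# isomirdiv

Isoform-level analysis of mature microRNAs (isomiRs) in small RNA-seq
cohorts: canonical offset naming, abundance filtering, per-miRNA
isoform-diversity statistics, survival stratification, seed-register target
scanning, and immunohistochemistry score quantification. The package was
built around the isomiR landscape of Wilms' tumor (nephroblastoma), where the
*diversity* of a miRNA's isoforms — not just its abundance — behaves as a
prognostic marker, but every stage is generic over the tab-separated count
and clinical dialects it documents.

## The analysis

An isomiR is written `<name> <offset5>|<offset3>`, where the two signed
integers are the distances (nt) of its 5' and 3' termini from the archetype
termini on the precursor hairpin (positive = downstream). `miR-455-5p 0|0`
is the archetype; `miR-455-5p 0|1` carries one extra templated 3' base.

The pipeline mirrors a tumor/normal cohort analysis:

1. **Filter** — keep isomiRs with more than 100 reads in at least one sample
   (≈12 RPM at the cohort's 8.9 M mean depth).
2. **Diversity** — per miRNA *m* and sample *s*, count distinct isomiRs
   observed; keep miRNAs whose across-sample median count is ≥ 3; tabulate
   pooled per-tissue categories {1, 2–9, ≥10} and compare tissues with a
   Pearson χ² test.
3. **Differential diversity** — per-miRNA Welch *t*-test of isoform counts
   between tumor/normal (α = 0.01) and unfavorable/favorable histology
   (α = 0.05); candidates must also pass a two-sided fold-change band
   (FC > 2 or < ½); the final hits are the intersection of both comparisons.
4. **Survival** — samples split at the median into "more"/"less" diversity
   groups; Kaplan–Meier curves with log-rank tests, and Cox proportional
   hazards (Efron ties) univariately and with histology as covariate.
5. **Target scan** — UTR windows reverse-complementary to miRNA seed
   positions 2–8 with ≤1 mismatch (G:U wobble counts as a mismatch) are
   candidate sites; each carries an extended-duplex pairing score
   (Watson–Crick +1, wobble +0.5) so that 3'-extended isoforms with an
   unchanged seed can still gain "effective" sites through 3'-supplementary
   pairing. A dinucleotide-preserving shuffle null calibrates the
   effective-site score threshold.
6. **IHC** — immunoreactivity score (intensity 0–3 × proportion bin 0–4)
   and H-score (Σ intensity × percent, 0–300), with two-rater
   reconciliation and *t*/ANOVA group comparisons.

A fully seeded synthetic-cohort generator (`isomirdiv.synthetic`) emulates
the statistical structure the analysis assumes — zero-truncated Poisson
isoform counts with planted group differences, negative-binomial reads with
library-size scaling, exponential survival with group-dependent hazards, and
UTRs with manifest-recorded planted seed sites — so every stage is testable
without any cohort download.

## Worked example

```python
from isomirdiv import RunConfig, SimConfig, run_pipeline

cfg = RunConfig(outdir="demo_run", seed=1,
                sim=SimConfig(n_tumor=60, n_normal=60, n_mirnas=20, n_signal=2))
summary = run_pipeline(cfg)
print(summary["candidates_shared"])
print(round(summary["survival"]["logrank_p"], 5))
print(summary["survival"]["cox_multivariable"])
print(summary["scan"])
```

prints

```
['mir-001', 'mir-002']
0.00532
{'diversity_group_more': 0.6239958082380803, 'histology_unfavorable': 3.157518312039245}
{'archetype': 'miR-455-5p 0|0', 'isoform': 'miR-455-5p 0|1',
 'effective_archetype': 4, 'effective_isoform': 5, 'delta': 1}
```

The two miRNAs with a planted 3-fold diversity difference are exactly the
candidate intersection. Patients in the "more"-diversity group have a lower
hazard (HR 0.62, i.e. ≈1.6-fold risk for the "less" group, planted 2.0 at
this small n), unfavorable histology carries ≈3-fold risk (planted 3.0), and
the log-rank test separates the diversity groups at p ≈ 0.005. On a planted
UTR the 3'-extended isoform gains one effective site over its archetype
(5 vs 4) although both share identical seed hits — the gain comes entirely
from 3'-supplementary pairing.

The same pipeline runs from the shell:

```bash
isomirdiv run --seed 1 --out demo_run
isomirdiv simulate --seed 1 --out demo_cohort
isomirdiv scan --mirna UAUGUGCCUUUGGACUACAUCG --utrs demo_cohort/utrs.fa --out hits.tsv
```

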