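# nc886 — bimodality-aware methylation analysis of a polymorphically imprinted locus

The human *nc886* locus (*VTRNA2-1*, chr5:136,078,784–136,080,957, GRCh38) is
polymorphically imprinted: in blood, ~75% of individuals carry a methylated
maternal allele — a DMR beta value near 0.5 across eleven 450K/EPIC probes —
while ~25% carry two unmethylated alleles (beta near 0). A few percent sit in
an intermediate band (0.2–0.4) and ~0.1% above 0.6. This bimodal structure
breaks the core assumption of standard EWAS practice, which models beta values
as continuous and approximately normal: in small case–control settings, random
imbalance of epigenotypes between groups alone produces nominally significant
differences with |Δβ| ≥ 0.3 under the null.

This package is for epigenomics analysts who work with this locus (or any
similarly bimodal epiallele). It provides:

- **Epigenotype classification** (`nc886.epigenotyping`): per-sample DMR
  summary (median over the 11 probes) and assignment to
  `non_methylated` [0, 0.20] / `intermediate` (0.20, 0.40] /
  `imprinted` (0.40, 0.60] / `over_methylated` (0.60, 1].
- **Cohort statistics** (`nc886.cohort_stats`): prevalence with Wilson score
  intervals; r×c categorical tests (Pearson χ² without continuity correction,
  exact fallback for near-empty cells); the closed-form probability
  *p*ⁿ that a group of *n* is all one epigenotype; expression-by-epigenotype
  fold changes (non-methylated individuals express ~two-fold relative to
  imprinted ones).
- **False-positive simulation** (`nc886.fp_simulation`): Monte-Carlo null
  case–control simulation of spurious-hit rates (p < α AND |Δβ| ≥ 0.3) and a
  deterministic scan over group compositions.
- **Paired tumour–normal analysis** (`nc886.paired_analysis`): per-pair
  Δ = tumour − normal summary beta categorised at a 2% threshold, and
  cohort-level pattern classes (bimodal maintained / hyper- or
  hypomethylation shift / pattern lost).
- **Synthetic data** (`nc886.synthetic_data`): a mixture-model generator with
  tissue presets and ground-truth tables, so every stage is testable without
  downloads.
- **IO + CLI** (`nc886.io`, `nc886.cli`): plain-TSV and GEO series-matrix
  beta readers, sample sheets, and an `nc886` command with subcommands
  `generate`, `classify`, `prevalence`, `associate`, `simulate-fp`,
  `paired`, `report`.

## Worked example

```python
from nc886 import (make_config, generate_cohort, classify_cohort,
                   prevalence_with_ci, compare_groups,
                   all_one_category_probability)

config = make_config("blood")                       # 75% imprinted mixture
matrix, truth, expr = generate_cohort(config, 10_000, seed=886)
calls, summary = classify_cohort(matrix)            # median over 11 probes
est = prevalence_with_ci(summary, "imprinted")
print(f"imprinted: {est.proportion:.1%} ({est.ci_lower:.1%}-{est.ci_upper:.1%})")
```

prints

```
imprinted: 75.0% (74.1%-75.8%)
```

i.e. classification recovers the generating prevalence (truth agreement is
99.9% per sample). The small-cohort hazard in numbers:

```python
print(all_one_category_probability(0.75, 6))   # 0.17798 -> "18%"
print(compare_groups([[8, 6], [12, 2]]))       # chi2 = 2.8, p = 0.094
```

With six cases and six controls drawn from the same population, one group is
entirely imprinted 18% of the time, and four non-methylated individuals in
the other group already produce Δβ = 0.3133 with p ≈ 0.01 — a textbook
spurious hit. The null simulation
(`analysis/03_small_cohort_false_positives.py`) measures a spurious-hit rate
of 0.0108 ± 0.0010 for the bimodal blood mixture at 6-vs-6 versus exactly 0
for a unimodal control locus, while the categorical imprinted-vs-others test
stays below its nominal α.

## Analysis pipeline

Numbered drivers under `analysis/` run the full study on synthetic cohorts
and write small tables under `results/` (bulky per-sample matrices go to
`scratch/`, regenerated on demand):

1. `01_generate_cohorts.py` — blood cohort (n = 10,000) and tissue presets.
2. `02_classify_epigenotypes.py` — classification, prevalence, expression
   coupling (fold change 2.01 at the default settings).
3. `03_small_cohort_false_positives.py` — composition probability, worked
   χ² example, composition scan, null simulation.
4. `04_paired_tumour_normal.py` — 46-pair cohort with a 30/10/6
   hypo/stable/hyper split, recovered exactly (65.2% / 21.7% / 13.0%) from
   the betas at the 0.02 threshold; pattern classes per tissue.

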