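# Methods

## The locus and the classification model

*nc886* (*VTRNA2-1*) is the only known human gene whose imprinting is
polymorphic rather than universal. Its ~2.2 kb differentially methylated
region (chr5:136,078,784–136,080,957, GRCh38) is summarised on Illumina
450K/EPIC arrays by eleven CpG probes (cg07158503, cg11608150, cg06478886,
cg04481923, cg18678645, cg06536614, cg25340688, cg26896946, cg00124993,
cg08745965, cg18797653). A sample's DMR summary beta is the **median** of
its non-missing probe betas (the median is robust to single-probe dropout
and outliers; the mean is available as an option). A call requires at least
`min_probes = 3` of the 11 probes — enough to tolerate array QC dropout
while preventing single-probe calls.

Summary betas are assigned to four epigenotype bins:

| category        | bin          | biology                                   |
|-----------------|--------------|-------------------------------------------|
| non_methylated  | [0, 0.20]    | both alleles unmethylated                  |
| intermediate    | (0.20, 0.40] | chimeric methylation, not cell-type driven |
| imprinted       | (0.40, 0.60] | one methylated (maternal) allele           |
| over_methylated | (0.60, 1]    | paternal allele partially methylated too   |

Thresholds 0.20 / 0.40 / 0.60 implement the in-text band definitions
(intermediate 20–40%, over-methylated strictly above 60%); they are
configurable via `ThresholdScheme`. A beta exactly at a threshold belongs
to the lower category — so "over 60%" means strictly above 0.60 — giving a
deterministic, documented tie-break. Samples with too few probes are
`unclassified`, excluded from binary labels, and counted.

## Categorical statistics

Prevalence intervals use the **Wilson score** method, which behaves sensibly
at the n < 100 cohort sizes typical of population surveys of this locus
(Wald intervals overshoot near the 0.75/0.88 prevalences involved).

Association tests on epigenotype contingency tables use the **Pearson
chi-squared test without continuity correction**. The convention is pinned
by the worked 2×2 example — 8 vs 12 imprinted individuals among 14 cases and
14 controls gives χ² = 2.8, p = 0.094 (reported as 0.09); Yates correction
would give ~0.21 instead. For 2×2 tables with an expected cell count below 3
the two-sided exact (hypergeometric) test is substituted and flagged. The
threshold of 3 rather than the textbook 5 is deliberate: the 8-vs-12 table
has minimum expected count 4 and is conventionally tested by chi-squared,
while tables with near-empty cells (e.g. a 6/0 row) genuinely need the exact
test. The fallback threshold is a parameter. Note that the exact test's
discreteness makes its p value differ from the chi-squared p by up to ~0.05
at mid-range p even on well-populated tables; the two coincide closely
(within 0.02) in the decision-relevant p < 0.03 range, which the test suite
asserts on generated tables.

The probability that a group of *n* individuals drawn independently from a
population is entirely of one epigenotype with prevalence *p* is *pⁿ*:
0.75⁶ = 0.178 (~18%) for an all-imprinted group of six. The default
semantics designate one group (matching *pⁿ*); an either-group variant
(2p⁶ − p¹², ≈ 32%) is available and labelled.

Expression comparisons use the two-sided Wilcoxon rank-sum test (RNA
abundances are not assumed normal) and report the ratio of group means.

## The synthetic-data generator

Each sample's true epigenotype is drawn from the category prevalences, a
latent DMR beta from that category's component, and probe betas as
latent + independent Gaussian noise, clipped to [0, 1] (clip events are
counted in the truth table's `attrs`). Defaults for blood:

| parameter | default | basis |
|---|---|---|
| prevalences | 0.75 / 0.228 / 0.02 / 0.002 | documented ~75% imprinted, ~25% non-methylated split, 1–6% intermediate (2% chosen as the mid-low value), ~0.1–0.2% over-methylated |
| imprinted component | Normal(0.50, 0.03) | tight cluster at 50% methylation |
| non-methylated component | Normal(0.03, 0.02) | "close to 0%" |
| intermediate component | Uniform(0.20, 0.40) | the stated band, no finer structure documented |
| over-methylated component | Uniform(0.60, 0.80) | "over 60%" |
| probe noise sd | 0.01 | within-sample probe scatter, stand-in |
| n_probes | 11 | the DMR probe set |

No within-cluster dispersions are documented for this locus; the component
sds are stand-ins chosen to produce tight, well-separated clusters, and
every recovery tolerance in the test suite is stated relative to them.
Moment-matched Beta components are available (`family="beta"`) for
boundary-respecting realism; Gaussians are the default for analytic
tractability.

Tissue presets encode the documented departures from blood's bimodality:
`skeletal_muscle` (100% imprinted at 0.50), `cerebellum` (unimodal
Normal(0.75, 0.05)), `breast`/`prostate` (unimodal Normal(0.50, 0.06) — the
bimodal pattern absent already in healthy tissue), `testis` (unimodal low,
Normal(0.10, 0.03)), and `unimodal_control` (all-imprinted comparator for
the false-positive simulation).

**Expression coupling.** Default is the allele-count model: two permissive
alleles (non-methylated) give relative level 2, one (imprinted) gives 1,
and intermediate/over-methylated samples interpolate as 2·(1 − β) — this
reproduces the two-fold difference exactly at zero noise. A fully
continuous option e(β) = 2·(1 − β) is provided; at the component means it
gives a fold of 1.94. Multiplicative lognormal noise (sd 0.2 on the log
scale) models biological and measurement variability. Because the
allele-count level is category-based, expression is strictly monotone in
latent beta only under the continuous coupling; under the default coupling
the monotonicity holds at the level of category means (the rare overlap of
an imprinted Gaussian tail with the intermediate band breaks strict
per-sample monotonicity, with no effect on any reported fold change).

**Paired cohorts.** Tumour latent betas are normal latent plus a drawn
shift. Shift-category counts are apportioned exactly by largest remainder
(so a 30/46–10/46–6/46 spec on 46 pairs yields exactly 30/10/6), and each
drawn magnitude is assigned headroom-aware — a sample cannot be
demethylated below 0 or methylated above 1 — falling back to the
most-headroom sample (with clipping) only when no sample can absorb the
shift. Hypomethylating magnitudes default to Uniform(0.05, 0.35), the
documented within-patient shifts being of this order; stable pairs get zero
shift.

## False-positive simulation

`run_null_simulation` draws cases and controls from the same population, so
every "hit" is spurious. Per replicate it computes the group mean difference
of summary betas (Δβ), the pooled-variance two-sample t p value (the
linear-model equivalent that continuous analyses apply; Welch optional), and
the categorical imprinted-vs-others test p value. A **spurious hit** is the
conjunction p < α AND |Δβ| ≥ 0.3, since differential-methylation practice
filters on both significance and effect size. Replicates where both groups
have identical betas are counted as degenerate; categorical tables with a
zero margin (no epigenotype variation at all) are untestable and score no
hit. One master seed drives a single generator stream; reports are
bit-identical across reruns. Default problem size is 6 + 6 samples and
10,000 replicates (runs in under a second; rates carry Monte-Carlo standard
errors √(r(1−r)/R)).

`composition_significance_scan` is the deterministic counterpart: with one
group all imprinted (betas at the 0.50 component mean) and k of n in the
other group non-methylated (0.03), Δβ = k·(0.50 − 0.03)/n — linear in k —
and the t test is evaluated on those exact values (the mixture itself
provides within-group variance; k = 0 is degenerate and flagged, and
optional within-category noise can be added under a seed). At n = 6 the
scan shows k = 3 giving p = 0.0493 — sitting at the 0.05 boundary, which is
why the scan reports p values rather than asserting significance at any
particular k — and k = 4 giving Δβ = 0.3133 with p = 0.010.

## Paired analysis and pattern classes

Per-pair deltas are tumour − normal summary betas (hypomethylation
negative), categorised at a threshold of 0.02 (the "2%" convention):
hypomethylated below −0.02, hypermethylated above +0.02, stable otherwise.
Pairs lacking a summary on either side are excluded and counted.

Cohort pattern classes are assigned from category fractions by explicit,
overridable rules evaluated in order (`PatternRules`): **bimodal_maintained**
if the imprinted and non-methylated fractions each retain ≥ 50% of the
reference tissue's expectation and the outside-bin fraction (intermediate +
over-methylated) is < 0.2; **hypermethylation_shift** /
**hypomethylation_shift** if the over-methylated / non-methylated fraction
exceeds the reference by ≥ 0.2; otherwise **pattern_lost** (which also
covers outside-bin fractions ≥ 0.3); **unimodal_baseline** when the
reference itself is not bimodal. The qualitative cancer-cohort descriptions
these classes operationalise come with no numeric rules, so the thresholds
are this package's own, always reported alongside the underlying fractions,
and the class is a pure function of those fractions.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline recovers the parameters of the
documented mixture structure — prevalences, the two-fold expression ratio,
paired shift splits — and that the continuous-vs-categorical false-positive
contrast behaves as the theory predicts. They do not validate behaviour on
real arrays: the generator draws probes i.i.d. around a common latent value
(no probe-specific biases, no spatial correlation along the DMR, no
cell-composition effects, no batch structure), uses symmetric Gaussian
components rather than the skewed clusters real beta values show near the
boundaries, and models no covariates (age, sex, ancestry). Classifications
of real cohorts near the 0.20/0.40/0.60 thresholds will be sensitive to the
upstream normalisation pipeline, which this package deliberately does not
perform (no IDAT processing).

## Problem sizes and numerical choices

Default analysis sizes — 10,000-sample cohorts for prevalence recovery,
10,000 simulation replicates, 2,000 cohorts for interval-coverage checks,
46 pairs for the paired worked example — were chosen so each quantity's
Monte-Carlo error is well inside the tolerance being asserted while the
whole suite stays interactive. Betas are processed as float64 fractions in
[0, 1]; percentages appear only at IO boundaries (`--percent` on input,
presentation on output). Medians of even-length probe sets are the mean of
the middle pair. All randomness flows through `numpy.random.default_rng`
seeded explicitly; nothing reads global random state.
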