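"""False-positive risk of treating a bimodal methylation locus as continuous.

Genome-wide methylation analyses typically model beta values as continuous,
approximately normal variables.  At a bimodal locus like nc886 this breaks
down: in a small case-control study the random imbalance of epigenotypes
between groups alone can produce a nominally significant mean difference
with a large effect size (|delta-beta| >= 0.3), i.e. a spurious hit under
the null.  This module quantifies that risk by Monte Carlo (cases and
controls drawn from the same population) and by deterministic enumeration
of group compositions, and contrasts the continuous-test spurious-hit rate
with the categorical imprinted-vs-others test, whose type-I error stays at
the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import compare_groups
from .epigenotyping import CATEGORIES, ThresholdScheme, classify_betas
from .synthetic_data import SyntheticConfig, draw_latent_betas, make_config

__all__ = [
    "SimulationSpec",
    "SpuriousHitReport",
    "run_null_simulation",
    "composition_significance_scan",
]

_IMPRINTED = CATEGORIES.index("imprinted")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of a null case-control simulation at a single locus."""

    config: SyntheticConfig = field(default_factory=make_config)
    n_cases: int = 6
    n_controls: int = 6
    replicates: int = 10_000
    delta_threshold: float = 0.3
    alpha: float = 0.05
    seed: int = 0
    #: "pooled" is the equal-variance two-sample comparison equivalent to the
    #: linear-model fit that continuous analyses use; "welch" is the option.
    continuous_test: str = "pooled"
    #: "designated" counts replicates where the case group is all imprinted
    #: (matching prevalence**n_cases); "either" counts either group.
    extreme_group: str = "designated"
    scheme: ThresholdScheme = field(default_factory=ThresholdScheme)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 <= self.delta_threshold <= 1.0):
            raise ValueError("delta_threshold must be in [0, 1]")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 samples per group")
        if self.continuous_test not in ("pooled", "welch"):
            raise ValueError("continuous_test must be 'pooled' or 'welch'")
        if self.extreme_group not in ("designated", "either"):
            raise ValueError("extreme_group must be 'designated' or 'either'")


@dataclass(frozen=True)
class SpuriousHitReport:
    """Spurious-hit rates under the null, with Monte-Carlo standard errors.

    A spurious hit for the continuous route is the conjunction p < alpha AND
    |delta-beta| >= delta_threshold, mirroring the p-value-plus-effect-size
    filter of differential-methylation practice.
    """

    rate_continuous: float
    rate_categorical: float
    rate_extreme_composition: float
    se_continuous: float
    se_categorical: float
    se_extreme_composition: float
    n_degenerate: int
    n_untestable_categorical: int
    spec: SimulationSpec

    def to_dict(self) -> dict:
        return {
            "rate_continuous": self.rate_continuous,
            "rate_categorical": self.rate_categorical,
            "rate_extreme_composition": self.rate_extreme_composition,
            "se_continuous": self.se_continuous,
            "se_categorical": self.se_categorical,
            "se_extreme_composition": self.se_extreme_composition,
            "n_degenerate": self.n_degenerate,
            "n_untestable_categorical": self.n_untestable_categorical,
            "spec": {
                "tissue": self.spec.config.tissue,
                "n_cases": self.spec.n_cases,
                "n_controls": self.spec.n_controls,
                "replicates": self.spec.replicates,
                "delta_threshold": self.spec.delta_threshold,
                "alpha": self.spec.alpha,
                "seed": self.spec.seed,
                "continuous_test": self.spec.continuous_test,
                "extreme_group": self.spec.extreme_group,
                "spurious_hit_definition": (
                    "p < alpha AND |delta_beta| >= delta_threshold under the "
                    "two-sample mean comparison of summary betas"
                ),
            },
        }


def _mc_se(rate: float, n: int) -> float:
    return float(np.sqrt(rate * (1.0 - rate) / n))


def run_null_simulation(spec: SimulationSpec) -> SpuriousHitReport:
    """Run the null case-control simulation and aggregate spurious-hit rates.

    Per replicate, cases and controls are drawn from the same population
    (so any detected difference is spurious), each sample's DMR summary beta
    is the median over the configured probes, and three quantities are
    evaluated: the continuous two-sample test with the effect-size filter,
    the categorical imprinted-vs-others test, and whether the designated
    group came out entirely imprinted.  Replicates where both groups have
    identical betas are counted as degenerate and score no continuous hit;
    categorical tables with a zero margin (no variation in epigenotype) are
    untestable and score no categorical hit.  Bit-reproducible from the seed.
    """
    cfg, reps = spec.config, spec.replicates
    m = spec.n_cases + spec.n_controls
    rng = np.random.default_rng(spec.seed)
    _, latent, _ = draw_latent_betas(cfg, reps * m, rng)
    probes = latent[None, :] + rng.normal(0, cfg.probe_noise_sd, (cfg.n_probes, reps * m))
    summary = np.median(np.clip(probes, 0.0, 1.0), axis=0).reshape(reps, m)
    cases, controls = summary[:, : spec.n_cases], summary[:, spec.n_cases :]

    delta = cases.mean(axis=1) - controls.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_p = stats.ttest_ind(
            cases, controls, axis=1, equal_var=spec.continuous_test == "pooled"
        ).pvalue
    degenerate = ~np.isfinite(t_p)
    hit_cont = (~degenerate) & (t_p < spec.alpha) & (np.abs(delta) >= spec.delta_threshold)

    cat = classify_betas(summary.ravel(), spec.scheme).reshape(reps, m)
    k_cases = (cat[:, : spec.n_cases] == _IMPRINTED).sum(axis=1)
    k_controls = (cat[:, spec.n_cases :] == _IMPRINTED).sum(axis=1)
    cache: dict[tuple[int, int], float | None] = {}
    hit_cat = np.zeros(reps, dtype=bool)
    n_untestable = 0
    for r in range(reps):
        key = (int(k_cases[r]), int(k_controls[r]))
        if key not in cache:
            table = [
                [key[0], spec.n_cases - key[0]],
                [key[1], spec.n_controls - key[1]],
            ]
            try:
                cache[key] = compare_groups(table).p_value
            except ValueError:  # zero margin: epigenotype invariant, untestable
                cache[key] = None
        p = cache[key]
        if p is None:
            n_untestable += 1
        else:
            hit_cat[r] = p < spec.alpha

    if spec.extreme_group == "designated":
        extreme = k_cases == spec.n_cases
    else:
        extreme = (k_cases == spec.n_cases) | (k_controls == spec.n_controls)

    r_cont = float(hit_cont.mean())
    r_cat = float(hit_cat.mean())
    r_ext = float(extreme.mean())
    return SpuriousHitReport(
        rate_continuous=r_cont,
        rate_categorical=r_cat,
        rate_extreme_composition=r_ext,
        se_continuous=_mc_se(r_cont, reps),
        se_categorical=_mc_se(r_cat, reps),
        se_extreme_composition=_mc_se(r_ext, reps),
        n_degenerate=int(degenerate.sum()),
        n_untestable_categorical=n_untestable,
        spec=spec,
    )


def composition_significance_scan(
    n_per_group: int,
    config: SyntheticConfig | None = None,
    test: str = "pooled",
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Enumerate group compositions and the significance each would reach.

    For k = 0..n, one group is entirely imprinted (betas at the imprinted
    component mean) and the other has k non-methylated members (betas at the
    non-methylated component mean).  Reports the group mean difference
    delta-beta at the canonical component means — linear in k with slope
    (mu_imprinted - mu_non_methylated)/n — and the two-sample test p value,
    optionally with within-category Gaussian noise added (seeded).  At k = 0
    and zero noise both groups are constant; the row is flagged degenerate
    and its p value is NaN.

    Returns a DataFrame with columns k, delta_beta, p_value, degenerate.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if test not in ("pooled", "welch"):
        raise ValueError("test must be 'pooled' or 'welch'")
    cfg = config if config is not None else make_config()
    mu_imp = cfg.components["imprinted"].a
    mu_non = cfg.components["non_methylated"].a
    rng = np.random.default_rng(seed)

    rows = []
    for k in range(n_per_group + 1):
        a = np.full(n_per_group, mu_imp)
        b = np.concatenate([np.full(k, mu_non), np.full(n_per_group - k, mu_imp)])
        delta = float(a.mean() - b.mean())
        if noise_sd > 0:
            a = a + rng.normal(0, noise_sd, n_per_group)
            b = b + rng.normal(0, noise_sd, n_per_group)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.ttest_ind(a, b, equal_var=test == "pooled").pvalue)
        degenerate = not np.isfinite(p)
        rows.append(
            {
                "k": k,
                "delta_beta": delta,
                "p_value": p if not degenerate else np.nan,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
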