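"""Synthetic methylation-array cohorts with the nc886 mixture structure.

Real blood cohorts show a bimodal distribution of DMR summary betas:
~75% of individuals imprinted (beta ~0.5), ~25% non-methylated (beta near
0), a few percent intermediate (0.2-0.4) and ~0.1% over-methylated (>0.6).
The generator draws each sample's true epigenotype from those prevalences,
draws a latent DMR beta from the category's component distribution, emits
per-probe betas as latent + independent noise (clipped to [0, 1]), and
couples RNA expression to the unmethylated-allele dose so that
non-methylated individuals express two-fold relative to imprinted ones.

Tissue presets cover the documented exceptions to blood's bimodality:
skeletal muscle (all imprinted at 50%), cerebellum (unimodal ~75%), and
the tissues where the bimodal pattern is absent already in healthy samples
(breast, prostate near 50%; testis low).

Component dispersions are stand-ins chosen to produce tight, well-separated
clusters; they are configurable and all recovery tolerances in the test
suite are stated relative to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .epigenotyping import CATEGORIES, BetaMatrix, DEFAULT_PROBES

__all__ = [
    "Component",
    "SyntheticConfig",
    "ShiftSpec",
    "PRESETS",
    "make_config",
    "generate_cohort",
    "generate_paired_cohort",
    "draw_latent_betas",
    "relative_expression",
]


@dataclass(frozen=True)
class Component:
    """One mixture component over latent DMR betas.

    ``kind`` is ``"normal"`` (a = mean, b = sd) or ``"uniform"`` (a = low,
    b = high).  Normal components may be swapped for moment-matched Beta
    distributions via ``SyntheticConfig.family = "beta"``.
    """

    kind: str
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "uniform"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        if self.kind == "normal" and self.b < 0:
            raise ValueError("normal component sd must be >= 0")
        if self.kind == "uniform" and not (0 <= self.a <= self.b <= 1):
            raise ValueError("uniform component bounds must satisfy 0 <= low <= high <= 1")

    def draw(self, n: int, rng: np.random.Generator, family: str = "gaussian") -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, n)
        if family == "beta" and self.b > 0:
            # moment-matched Beta(alpha, beta) with mean a and sd b
            m, v = self.a, self.b**2
            nu = m * (1 - m) / v - 1
            if nu <= 0:
                raise ValueError("beta family requires sd^2 < mean*(1-mean)")
            return rng.beta(m * nu, (1 - m) * nu, n)
        return rng.normal(self.a, self.b, n)


_DEFAULT_COMPONENTS: dict[str, Component] = {
    "imprinted": Component("normal", 0.50, 0.03),
    "non_methylated": Component("normal", 0.03, 0.02),
    "intermediate": Component("uniform", 0.20, 0.40),
    "over_methylated": Component("uniform", 0.60, 0.80),
}

_BLOOD_PREVALENCES: dict[str, float] = {
    "imprinted": 0.75,
    "non_methylated": 0.228,
    "intermediate": 0.02,
    "over_methylated": 0.002,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic cohort's statistical structure."""

    prevalences: Mapping[str, float] = field(default_factory=lambda: dict(_BLOOD_PREVALENCES))
    components: Mapping[str, Component] = field(default_factory=lambda: dict(_DEFAULT_COMPONENTS))
    probe_noise_sd: float = 0.01
    n_probes: int = 11
    probe_ids: tuple[str, ...] = DEFAULT_PROBES.probe_ids
    tissue: str = "blood"
    expression_base: float = 100.0
    #: "allele_count" gives level 2 for non-methylated and 1 for imprinted
    #: (two vs one permissive allele); "continuous" uses e(beta) = 2*(1-beta).
    expression_coupling: str = "allele_count"
    expression_lognorm_sd: float = 0.2
    family: str = "gaussian"
    seed: int | None = None

    def __post_init__(self) -> None:
        prev = dict(self.prevalences)
        unknown = set(prev) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in prevalences: {sorted(unknown)}")
        if any(v < 0 for v in prev.values()):
            raise ValueError("prevalences must be >= 0")
        if abs(sum(prev.values()) - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1, got {sum(prev.values())}")
        if self.probe_noise_sd < 0:
            raise ValueError("probe_noise_sd must be >= 0")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.expression_coupling not in ("allele_count", "continuous"):
            raise ValueError("expression_coupling must be 'allele_count' or 'continuous'")
        if self.family not in ("gaussian", "beta"):
            raise ValueError("family must be 'gaussian' or 'beta'")
        object.__setattr__(self, "prevalences", prev)
        object.__setattr__(self, "components", dict(self.components))
        pids = tuple(self.probe_ids)[: self.n_probes]
        if len(pids) < self.n_probes:
            pids = pids + tuple(
                f"probe{i:03d}" for i in range(len(pids), self.n_probes)
            )
        object.__setattr__(self, "probe_ids", pids)


PRESETS: dict[str, dict] = {
    "blood": {},
    "skeletal_muscle": {
        "tissue": "skeletal_muscle",
        "prevalences": {"imprinted": 1.0},
    },
    "cerebellum": {
        "tissue": "cerebellum",
        "prevalences": {"over_methylated": 1.0},
        "components": {**_DEFAULT_COMPONENTS, "over_methylated": Component("normal", 0.75, 0.05)},
    },
    "breast": {
        "tissue": "breast",
        "prevalences": {"imprinted": 1.0},
        "components": {**_DEFAULT_COMPONENTS, "imprinted": Component("normal", 0.50, 0.06)},
    },
    "prostate": {
        "tissue": "prostate",
        "prevalences": {"imprinted": 1.0},
        "components": {**_DEFAULT_COMPONENTS, "imprinted": Component("normal", 0.50, 0.06)},
    },
    "testis": {
        "tissue": "testis",
        "prevalences": {"non_methylated": 1.0},
        "components": {**_DEFAULT_COMPONENTS, "non_methylated": Component("normal", 0.10, 0.03)},
    },
    "unimodal_control": {
        "tissue": "unimodal_control",
        "prevalences": {"imprinted": 1.0},
    },
}


def make_config(preset: str = "blood", **overrides) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a tissue preset plus overrides.

    Presets: blood (bimodal, 75% imprinted / 22.8% non-methylated / 2%
    intermediate / 0.2% over-methylated), skeletal_muscle (100% imprinted),
    cerebellum (unimodal ~0.75), breast / prostate (unimodal near 0.5),
    testis (unimodal low), unimodal_control (all-imprinted comparator for
    false-positive simulations).
    """
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    kwargs = {**PRESETS[preset], **overrides}
    prev = kwargs.get("prevalences")
    if prev is not None and abs(sum(prev.values()) - 1.0) <= 1e-9:
        # allow sparse prevalence dicts; absent categories get 0
        kwargs["prevalences"] = {k: prev.get(k, 0.0) for k in CATEGORIES}
    return SyntheticConfig(**kwargs)


def draw_latent_betas(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw (category indices, latent betas, clip count) for n samples."""
    probs = np.array([config.prevalences.get(c, 0.0) for c in CATEGORIES])
    cat_idx = rng.choice(len(CATEGORIES), size=n, p=probs)
    latent = np.empty(n)
    for i, cat in enumerate(CATEGORIES):
        mask = cat_idx == i
        if mask.any():
            latent[mask] = config.components[cat].draw(int(mask.sum()), rng, config.family)
    n_clipped = int(np.sum((latent < 0) | (latent > 1)))
    return cat_idx, np.clip(latent, 0.0, 1.0), n_clipped


def relative_expression(
    cat_idx: np.ndarray, latent: np.ndarray, coupling: str = "allele_count"
) -> np.ndarray:
    """Noise-free relative RNA level given true category and latent beta.

    allele_count: non-methylated samples express from two permissive alleles
    (level 2), imprinted from one (level 1); intermediate and over-methylated
    samples interpolate linearly in the unmethylated-allele fraction,
    level = 2*(1 - latent).  continuous: level = 2*(1 - latent) throughout.
    """
    level = 2.0 * (1.0 - latent)
    if coupling == "allele_count":
        level = level.copy()
        level[cat_idx == CATEGORIES.index("non_methylated")] = 2.0
        level[cat_idx == CATEGORIES.index("imprinted")] = 1.0
    return level


def _probe_matrix(
    latent: np.ndarray, config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    betas = latent[None, :] + rng.normal(0, config.probe_noise_sd, (config.n_probes, latent.size))
    n_clipped = int(np.sum((betas < 0) | (betas > 1)))
    return np.clip(betas, 0.0, 1.0), n_clipped


def generate_cohort(
    config: SyntheticConfig,
    n: int,
    seed: int | None = None,
    sample_prefix: str = "S",
) -> tuple[BetaMatrix, pd.DataFrame, pd.Series]:
    """Generate a cohort: (BetaMatrix, truth table, expression vector).

    The truth table records each sample's true category, latent beta and
    noise-free relative expression level; its ``attrs["n_clipped"]`` counts
    betas clipped to [0, 1].  Fully reproducible from ``seed`` (falling back
    to ``config.seed``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    cat_idx, latent, clip_lat = draw_latent_betas(config, n, rng)
    betas, clip_probe = _probe_matrix(latent, config, rng)
    level = relative_expression(cat_idx, latent, config.expression_coupling)
    noise = (
        np.exp(rng.normal(0, config.expression_lognorm_sd, n))
        if config.expression_lognorm_sd > 0
        else np.ones(n)
    )
    expression = config.expression_base * level * noise

    sample_ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n)]
    matrix = BetaMatrix.from_arrays(config.probe_ids, sample_ids, betas)
    truth = pd.DataFrame(
        {
            "true_category": [CATEGORIES[i] for i in cat_idx],
            "latent_beta": latent,
            "relative_expression": level,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth.attrs["n_clipped"] = clip_lat + clip_probe
    return matrix, truth, pd.Series(expression, index=sample_ids, name="expression")


@dataclass(frozen=True)
class ShiftSpec:
    """Tumour-normal shift structure for paired cohorts.

    Fractions must sum to 1.  Magnitudes are drawn uniformly from the given
    ranges; hypomethylating shifts are applied with negative sign, stable
    pairs get zero shift.
    """

    frac_hypo: float
    frac_stable: float
    frac_hyper: float
    hypo_magnitude: tuple[float, float] = (0.05, 0.35)
    hyper_magnitude: tuple[float, float] = (0.05, 0.20)

    def __post_init__(self) -> None:
        fr = (self.frac_hypo, self.frac_stable, self.frac_hyper)
        if any(f < 0 for f in fr):
            raise ValueError("shift fractions must be >= 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"shift fractions must sum to 1, got {sum(fr)}")


def _exact_counts(fractions: np.ndarray, n: int) -> np.ndarray:
    """Apportion n into integer counts matching fractions (largest remainder)."""
    raw = fractions * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def generate_paired_cohort(
    config: SyntheticConfig,
    n_pairs: int,
    shift_spec: ShiftSpec,
    seed: int | None = None,
) -> tuple[BetaMatrix, BetaMatrix, pd.DataFrame]:
    """Generate paired normal/tumour matrices with known shift truth.

    Shift-category counts are apportioned exactly (largest remainder), so a
    spec of (30/46, 10/46, 6/46) on 46 pairs yields exactly 30/10/6 pairs.
    Returns (normal BetaMatrix, tumour BetaMatrix, truth table); tumour
    sample ids are ``<pair>_T`` and normal ``<pair>_N``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    cat_idx, latent, _ = draw_latent_betas(config, n_pairs, rng)

    counts = _exact_counts(
        np.array([shift_spec.frac_hypo, shift_spec.frac_stable, shift_spec.frac_hyper]),
        n_pairs,
    )
    # Assign shifts headroom-aware: a sample cannot be demethylated below 0
    # or methylated above 1, so each drawn magnitude goes to a random sample
    # that can absorb it without clipping (falling back to the sample with
    # the most headroom when none can, in which case the shift is clipped).
    labels = np.full(n_pairs, "stable", dtype=object)
    shifts = np.zeros(n_pairs)
    unassigned = set(range(n_pairs))

    def _assign(magnitudes: np.ndarray, headroom: np.ndarray, label: str, sign: float) -> None:
        for mag in np.sort(magnitudes)[::-1]:
            feasible = [i for i in unassigned if headroom[i] >= mag]
            if feasible:
                i = int(rng.choice(feasible))
            else:
                i = max(unassigned, key=lambda j: headroom[j])
            unassigned.discard(i)
            labels[i] = label
            shifts[i] = sign * mag

    _assign(
        rng.uniform(*shift_spec.hypo_magnitude, int(counts[0])),
        latent,
        "hypomethylated",
        -1.0,
    )
    _assign(
        rng.uniform(*shift_spec.hyper_magnitude, int(counts[2])),
        1.0 - latent,
        "hypermethylated",
        +1.0,
    )

    tumour_latent = np.clip(latent + shifts, 0.0, 1.0)
    normal_betas, _ = _probe_matrix(latent, config, rng)
    tumour_betas, _ = _probe_matrix(tumour_latent, config, rng)

    pair_ids = [f"P{i + 1:04d}" for i in range(n_pairs)]
    normal = BetaMatrix.from_arrays(config.probe_ids, [p + "_N" for p in pair_ids], normal_betas)
    tumour = BetaMatrix.from_arrays(config.probe_ids, [p + "_T" for p in pair_ids], tumour_betas)
    truth = pd.DataFrame(
        {
            "normal_category": [CATEGORIES[i] for i in cat_idx],
            "normal_latent": latent,
            "tumour_latent": tumour_latent,
            "true_shift": shifts,
            "shift_category": labels,
        },
        index=pd.Index(pair_ids, name="pair_id"),
    )
    return normal, tumour, truth
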