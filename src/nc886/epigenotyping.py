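"""Per-sample epigenotype calling at the nc886 differentially methylated region.

The nc886 locus (chr5:136,078,784-136,080,957, GRCh38) is polymorphically
imprinted: roughly three quarters of individuals carry a methylated maternal
allele (beta ~0.5 across the DMR) while the remainder carry two unmethylated
alleles (beta near 0).  A small fraction of samples sit in an intermediate
band (0.2-0.4, chimeric methylation) or above 0.6 (gain on the paternal
allele).  This module summarises the DMR per sample from array beta values
and assigns each sample one of these categorical epigenotypes, which is the
unit every downstream analysis operates on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "UNCLASSIFIED",
    "ProbeSet",
    "BetaMatrix",
    "ThresholdScheme",
    "EpigenotypeCall",
    "CohortSummary",
    "DEFAULT_PROBES",
    "summarize_dmr",
    "classify_sample",
    "classify_cohort",
    "binarize_calls",
]

#: Epigenotype categories ordered by increasing methylation.
CATEGORIES = ("non_methylated", "intermediate", "imprinted", "over_methylated")
UNCLASSIFIED = "unclassified"

# The eleven 450K/EPIC probes conventionally used to summarise the nc886 DMR.
_NC886_PROBE_IDS = (
    "cg07158503",
    "cg11608150",
    "cg06478886",
    "cg04481923",
    "cg18678645",
    "cg06536614",
    "cg25340688",
    "cg26896946",
    "cg00124993",
    "cg08745965",
    "cg18797653",
)


@dataclass(frozen=True)
class ProbeSet:
    """A named set of array probes covering one genomic region.

    Coordinates are 1-based inclusive on the stated assembly.
    """

    probe_ids: tuple[str, ...]
    locus_label: str = "nc886"
    assembly: str = "GRCh38"
    chromosome: str = "chr5"
    start: int = 136078784
    end: int = 136080957

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("ProbeSet requires at least one probe id")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("ProbeSet probe_ids must be unique")
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))


DEFAULT_PROBES = ProbeSet(probe_ids=_NC886_PROBE_IDS)


class BetaMatrix:
    """Probe x sample matrix of methylation beta fractions in [0, 1].

    Thin validated wrapper around a pandas DataFrame (probes as index,
    samples as columns).  Missing values are allowed and represented as NaN.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value {arr[i, j]} out of [0, 1] at probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self.values = values.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @classmethod
    def from_arrays(
        cls,
        probe_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> "BetaMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float), index=list(probe_ids), columns=list(sample_ids)
        )
        return cls(frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.shape[0]} probes x {self.shape[1]} samples)"


@dataclass(frozen=True)
class ThresholdScheme:
    """Category bounds partitioning [0, 1] into the four epigenotype bins.

    Bins are lower-closed at 0 and otherwise upper-closed: a summary beta
    exactly equal to a threshold is assigned the lower category, so
    over-methylated means strictly above ``imprinted_max`` ("over 60%").

    Defaults follow the in-text band definitions: non-methylated up to 0.20,
    intermediate 0.20-0.40, imprinted 0.40-0.60, over-methylated above 0.60.
    """

    non_methylated_max: float = 0.20
    intermediate_max: float = 0.40
    imprinted_max: float = 0.60

    def __post_init__(self) -> None:
        t = (self.non_methylated_max, self.intermediate_max, self.imprinted_max)
        if not (0.0 < t[0] < t[1] < t[2] < 1.0):
            raise ValueError(
                f"thresholds must satisfy 0 < non_methylated_max < "
                f"intermediate_max < imprinted_max < 1, got {t}"
            )

    @property
    def edges(self) -> np.ndarray:
        return np.array(
            [self.non_methylated_max, self.intermediate_max, self.imprinted_max]
        )


@dataclass(frozen=True)
class EpigenotypeCall:
    """One sample's DMR summary beta and assigned category."""

    sample_id: str
    summary_beta: float | None
    n_probes_used: int
    category: str


@dataclass
class CohortSummary:
    """Category counts and fractions over the classified samples of a cohort."""

    counts: dict[str, int]
    total: int
    fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts do not sum to total")
        self.fractions = {
            k: (v / self.total if self.total else 0.0) for k, v in self.counts.items()
        }

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "total": self.total, "fractions": dict(self.fractions)}


def summarize_dmr(
    matrix: BetaMatrix,
    probes: ProbeSet = DEFAULT_PROBES,
    min_probes: int = 3,
    stat: str = "median",
) -> dict[str, float | None]:
    """Summarise the DMR per sample across the probe set.

    Returns a mapping sample_id -> summary beta (the median of non-missing
    probe betas by default; ``stat="mean"`` for the arithmetic mean), or
    ``None`` when fewer than ``min_probes`` values are available.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if stat not in ("median", "mean"):
        raise ValueError(f"stat must be 'median' or 'mean', got {stat!r}")
    present = [p for p in probes.probe_ids if p in matrix.values.index]
    if not present:
        raise KeyError(
            f"none of the {len(probes.probe_ids)} probes of "
            f"{probes.locus_label!r} are present in the matrix; "
            f"missing: {list(probes.probe_ids)}"
        )
    sub = matrix.values.loc[present]
    n_used = sub.notna().sum(axis=0)
    summary = sub.median(axis=0) if stat == "median" else sub.mean(axis=0)
    out: dict[str, float | None] = {}
    for sid in matrix.sample_ids:
        out[sid] = float(summary[sid]) if n_used[sid] >= min_probes else None
    return out


def classify_sample(summary_beta: float, scheme: ThresholdScheme = ThresholdScheme()) -> str:
    """Assign one summary beta to its epigenotype category.

    Deterministic bin lookup; a value exactly at a threshold goes to the
    lower category.
    """
    if not (0.0 <= summary_beta <= 1.0) or np.isnan(summary_beta):
        raise ValueError(f"summary beta {summary_beta} outside [0, 1]")
    idx = int(np.searchsorted(scheme.edges, summary_beta, side="left"))
    return CATEGORIES[idx]


def classify_betas(
    summary_betas: np.ndarray, scheme: ThresholdScheme = ThresholdScheme()
) -> np.ndarray:
    """Vectorised category index lookup (NaN-free input required).

    Returns integer indices into :data:`CATEGORIES`.
    """
    arr = np.asarray(summary_betas, dtype=float)
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("summary betas must lie in [0, 1] with no NaN")
    return np.searchsorted(scheme.edges, arr, side="left")


def classify_cohort(
    matrix: BetaMatrix,
    probes: ProbeSet = DEFAULT_PROBES,
    scheme: ThresholdScheme = ThresholdScheme(),
    min_probes: int = 3,
    stat: str = "median",
) -> tuple[list[EpigenotypeCall], CohortSummary]:
    """Classify every sample of a beta matrix; returns calls and a summary.

    Samples with too few probe values get category ``unclassified`` and are
    counted under that key in the summary.
    """
    if matrix.shape[1] == 0:
        raise ValueError("matrix has no samples")
    summaries = summarize_dmr(matrix, probes, min_probes=min_probes, stat=stat)
    present = [p for p in probes.probe_ids if p in matrix.values.index]
    n_used = matrix.values.loc[present].notna().sum(axis=0)
    calls: list[EpigenotypeCall] = []
    for sid in matrix.sample_ids:
        beta = summaries[sid]
        if beta is None:
            calls.append(EpigenotypeCall(sid, None, int(n_used[sid]), UNCLASSIFIED))
        else:
            calls.append(
                EpigenotypeCall(sid, beta, int(n_used[sid]), classify_sample(beta, scheme))
            )
    counts = Counter(c.category for c in calls)
    full = {k: counts.get(k, 0) for k in CATEGORIES + (UNCLASSIFIED,)}
    return calls, CohortSummary(counts=full, total=len(calls))


def binarize_calls(
    calls: Iterable[EpigenotypeCall], positive: set[str] | frozenset[str]
) -> tuple[dict[str, str], int]:
    """Collapse calls to two-level positive/other labels.

    ``positive`` is the category set treated as positive (typically
    ``{"imprinted"}``, the imprinted-vs-others dichotomy).  Unclassified
    samples are excluded; their count is returned alongside the labels.
    """
    positive = set(positive)
    if not positive:
        raise ValueError("positive category set must be non-empty")
    unknown = positive - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories in positive set: {sorted(unknown)}")
    labels: dict[str, str] = {}
    n_excluded = 0
    for call in calls:
        if call.category == UNCLASSIFIED:
            n_excluded += 1
            continue
        labels[call.sample_id] = "positive" if call.category in positive else "other"
    return labels, n_excluded


def calls_to_frame(calls: Sequence[EpigenotypeCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (sample_id, summary_beta, n_probes_used, category)."""
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "summary_beta": [c.summary_beta for c in calls],
            "n_probes_used": [c.n_probes_used for c in calls],
            "category": [c.category for c in calls],
        }
    )
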