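"""Readers and writers for beta matrices, sample sheets, configs and reports.

The canonical interchange format is a plain tab-separated beta matrix with
probes as rows and samples as columns, as GEO series matrices conventionally
distribute processed 450K/EPIC betas.  The GEO series-matrix dialect is
supported read-only: metadata lines beginning "!" are skipped and the table
is taken from between the table begin/end markers.  Betas are stored as
fractions in [0, 1]; percentage input is divided by 100 at parse time when
requested.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .epigenotyping import BetaMatrix

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "pairs_from_sheet",
    "read_run_config",
    "write_json",
]

_GEO_BEGIN = "!series_matrix_table_begin"
_GEO_END = "!series_matrix_table_end"


def _parse_table(text: str, path: Path, percent: bool) -> BetaMatrix:
    from io import StringIO

    frame = pd.read_csv(StringIO(text), sep="\t", index_col=0, na_values=["NA", "null"])
    frame.index = frame.index.astype(str).str.strip('"')
    frame.columns = frame.columns.astype(str).str.strip('"')
    frame.index.name = None
    frame.columns.name = None
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe ids {dups}")
    if frame.columns.has_duplicates:
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric cell ({exc})") from exc
    if percent:
        frame = frame / 100.0
    arr = frame.to_numpy()
    bad = (arr < 0) | (arr > 1)
    if np.any(bad & ~np.isnan(arr)):
        i, j = np.argwhere(bad & ~np.isnan(arr))[0]
        raise ValueError(
            f"{path}: beta value {arr[i, j]} out of [0, 1] at probe "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    return BetaMatrix(frame)


def read_beta_matrix(
    path: str | Path, dialect: str = "plain_tsv", percent: bool = False
) -> BetaMatrix:
    """Read a probe x sample beta matrix.

    ``dialect="plain_tsv"``: first column probe ids, header row sample ids.
    ``dialect="geo_series_matrix"``: GEO series-matrix file; "!"-prefixed
    metadata lines are skipped and the table is extracted from between the
    table markers.  ``percent=True`` divides all values by 100.
    """
    path = Path(path)
    if dialect not in ("plain_tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    if dialect == "geo_series_matrix":
        lines = text.splitlines()
        try:
            begin = next(i for i, l in enumerate(lines) if l.startswith(_GEO_BEGIN))
            end = next(i for i, l in enumerate(lines) if l.startswith(_GEO_END))
        except StopIteration:
            raise ValueError(f"{path}: series-matrix table markers not found") from None
        text = "\n".join(lines[begin + 1 : end])
    else:
        text = "\n".join(l for l in text.splitlines() if not l.startswith("!"))
    if not text.strip():
        raise ValueError(f"{path}: no table content")
    return _parse_table(text, path, percent)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    """Write a beta matrix as plain TSV (probes x samples)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a CSV sample sheet.

    Requires a ``sample_id`` column with unique values; ``group``,
    ``population``, ``pair_id``, ``tissue`` and any other columns are
    preserved as annotations.
    """
    sheet = pd.read_csv(path, dtype=str)
    if "sample_id" not in sheet.columns:
        raise ValueError(f"{path}: sample sheet needs a 'sample_id' column")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate sample_id {dup.tolist()}")
    return sheet


def pairs_from_sheet(
    sheet: pd.DataFrame, role_column: str = "group", normal_label: str = "normal"
) -> dict[str, tuple[str, str]]:
    """Extract pair_id -> (normal sample, tumour sample) from a sample sheet.

    Every non-empty pair_id must appear in exactly two rows, one with the
    normal label in ``role_column`` and one without.
    """
    if "pair_id" not in sheet.columns:
        raise ValueError("sample sheet has no 'pair_id' column")
    pairs: dict[str, tuple[str, str]] = {}
    for pair_id, rows in sheet.dropna(subset=["pair_id"]).groupby("pair_id"):
        if len(rows) != 2:
            raise ValueError(f"pair_id {pair_id!r} has {len(rows)} members, expected 2")
        normal = rows[rows[role_column] == normal_label]
        tumour = rows[rows[role_column] != normal_label]
        if len(normal) != 1 or len(tumour) != 1:
            raise ValueError(
                f"pair_id {pair_id!r} must have exactly one {normal_label!r} "
                f"and one other sample"
            )
        pairs[str(pair_id)] = (
            normal["sample_id"].iloc[0],
            tumour["sample_id"].iloc[0],
        )
    return pairs


def read_run_config(path: str | Path) -> dict:
    """Read a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
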