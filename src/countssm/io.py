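"""CSV/JSON input-output for diaries, fits and iteration traces.

The diary format is a tidy CSV with one row per day: an integer ``day``
column (contiguous), one non-negative integer ``count`` column, and one
non-negative dosage column per drug.  An optional ``date`` column (ISO
8601) is carried along but ignored by the math.  Missing values are
rejected — missing-data handling is a documented non-goal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import FilterOutput

__all__ = [
    "read_diary_csv",
    "write_diary_csv",
    "write_results",
    "export_iteration_traces",
]

_RESERVED = {"day", "count", "date"}


def read_diary_csv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read a diary CSV into ``(counts, controls, drug_names)``.

    Row numbers in error messages are 1-based data rows (the header is
    row 0).
    """
    df = pd.read_csv(path)
    if "day" not in df.columns or "count" not in df.columns:
        raise ValueError("diary CSV needs 'day' and 'count' columns")
    drug_cols = [c for c in df.columns if c not in _RESERVED]
    if not drug_cols:
        raise ValueError("diary CSV needs at least one dosage column")

    for col in ["day", "count", *drug_cols]:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"missing value in column {col!r} at row {bad[0] + 1}")

    days = df["day"].to_numpy()
    if not np.array_equal(days, np.arange(days[0], days[0] + len(days))):
        gaps = np.where(np.diff(days) != 1)[0]
        row = int(gaps[0]) + 2 if len(gaps) else 1
        raise ValueError(f"day column must be contiguous (problem near row {row})")

    counts = df["count"].to_numpy()
    if not np.allclose(counts, np.round(counts)):
        row = int(np.where(~np.isclose(counts, np.round(counts)))[0][0]) + 1
        raise ValueError(f"non-integer count at row {row}")
    if np.any(counts < 0):
        row = int(np.where(counts < 0)[0][0]) + 1
        raise ValueError(f"negative count at row {row}")

    controls = df[drug_cols].to_numpy(dtype=float)
    if np.any(controls < 0):
        r, c = np.argwhere(controls < 0)[0]
        raise ValueError(f"negative dosage in {drug_cols[c]!r} at row {int(r) + 1}")
    return counts.astype(int), controls, drug_cols


def write_diary_csv(path, counts, controls, names=None) -> None:
    """Write a diary CSV (inverse of :func:`read_diary_csv`)."""
    controls = np.asarray(controls, dtype=float)
    if controls.ndim == 1:
        controls = controls[:, None]
    names = names or [f"aed{j + 1}" for j in range(controls.shape[1])]
    df = pd.DataFrame({"day": np.arange(1, len(counts) + 1)})
    df["count"] = np.asarray(counts, dtype=int)
    for j, name in enumerate(names):
        df[name] = controls[:, j]
    df.to_csv(path, index=False)


def write_results(path, result) -> None:
    """Serialize a fit / ensemble / regression result to JSON.

    Accepts anything exposing ``to_dict()`` or a plain dict.
    """
    obj = result.to_dict() if hasattr(result, "to_dict") else result

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)!r}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def export_iteration_traces(path, filter_output: FilterOutput) -> None:
    """Write the inner-iteration convergence traces as a long CSV.

    Columns ``t`` (1-based time), ``i`` (1-based iteration index) and
    ``relative_change``, one row per recorded iteration — the numeric
    content behind convergence-vs-iteration plots.
    """
    rows = []
    for t, trace in enumerate(filter_output.iter_traces, start=1):
        for i, rel in enumerate(trace, start=1):
            rows.append((t, i, rel))
    pd.DataFrame(rows, columns=["t", "i", "relative_change"]).to_csv(
        path, index=False
    )
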