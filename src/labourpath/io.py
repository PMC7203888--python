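"""CSV/JSON input-output and report rendering.

Dialects (all UTF-8, comma-separated, point decimals, header row):

* **per-woman CSV** — one row per woman; one 0/1 column per protocol label,
  optional ``woman_id`` and ``robson_class`` columns, and optionally raw
  ``amniotomy``/``oxytocin`` columns which are OR-merged into augmentation;
* **path-count CSV** — one 0/1 column per protocol label plus ``count``;
* **Robson CSV** — columns ``class,women,caesareans``.

Human-readable rendering uses point decimals; ``paper_style=True`` switches
to comma decimals for side-by-side checking against typewritten clinical
tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .decompose import StepwiseDecomposition
from .measures import round_half_away
from .protocol import (
    DEFAULT_PROTOCOL,
    InterventionProtocol,
    PathCountTable,
    RecordValidationError,
    path_table_from_records,
)
from .robson import RobsonClassCounts

__all__ = [
    "read_women_csv",
    "read_path_counts_csv",
    "write_path_counts_csv",
    "read_robson_csv",
    "write_robson_csv",
    "render_stepwise_text",
    "stepwise_to_csv",
]


def read_women_csv(
    path, protocol: InterventionProtocol = DEFAULT_PROTOCOL,
    stratify_by: str | None = None,
):
    """Load a per-woman CSV and aggregate it into a path-count table."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise RecordValidationError(f"malformed CSV {path}: {exc}") from exc
    return path_table_from_records(df, protocol, stratify_by=stratify_by)


def read_path_counts_csv(
    path, protocol: InterventionProtocol = DEFAULT_PROTOCOL
) -> PathCountTable:
    """Load a path-count CSV (protocol columns + ``count``)."""
    df = pd.read_csv(path)
    missing = [c for c in (*protocol.labels, "count") if c not in df.columns]
    if missing:
        raise RecordValidationError(
            f"{path}: missing columns {missing}", column=missing[0]
        )
    counts = {}
    for i, row in df.iterrows():
        flags = tuple(int(row[l]) for l in protocol.labels)
        if any(f not in (0, 1) for f in flags):
            raise RecordValidationError(
                f"{path} line {i + 2}: non-binary path {flags}", row=i
            )
        counts[flags] = counts.get(flags, 0) + int(row["count"])
    return PathCountTable(protocol, counts)


def write_path_counts_csv(table: PathCountTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_robson_csv(path) -> list[RobsonClassCounts]:
    df = pd.read_csv(path)
    required = ("class", "women", "caesareans")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordValidationError(
            f"{path}: missing columns {missing}", column=missing[0]
        )
    return [
        RobsonClassCounts(str(r["class"]), int(r["women"]), int(r["caesareans"]))
        for _, r in df.iterrows()
    ]


def write_robson_csv(classes: Sequence[RobsonClassCounts], path) -> None:
    pd.DataFrame(
        [
            {"class": c.label, "women": c.women, "caesareans": c.caesareans}
            for c in classes
        ]
    ).to_csv(path, index=False)


def _fmt(x: float, nd: int, paper_style: bool) -> str:
    if x is None:
        return "-"
    s = f"{round_half_away(x, nd):.{nd}f}"
    return s.replace(".", ",") if paper_style else s


def render_stepwise_text(
    dec: StepwiseDecomposition, paper_style: bool = False
) -> str:
    """Render a stepwise decomposition as the familiar replacement grid:
    one column per step, rows for the functional value, the partial
    differences and the scaled relative contributions."""
    headers = ["", "cohort 1"] + [
        f"& {'->'.join(p)}" for p in dec.order
    ] + ["cohort 2"]
    value_row = (
        [dec.functional]
        + [_fmt(v, 3, paper_style) for v in dec.step_values]
        + [_fmt(dec.step_values[-1], 3, paper_style)]
    )
    delta_row = (
        ["partial diff."]
        + [""]
        + [_fmt(d, 3, paper_style) for d in dec.deltas]
        + [""]
    )
    if dec.contributions is None:
        contrib = ["-"] * len(dec.deltas)
    else:
        contrib = [_fmt(c, 2, paper_style) for c in dec.contributions]
    contrib_row = ["rel. contrib."] + [""] + contrib + [""]

    rows = [headers, value_row, delta_row, contrib_row]
    widths = [max(len(r[i]) for r in rows) for i in range(len(headers))]
    return "\n".join(
        "  ".join(cell.rjust(w) for cell, w in zip(row, widths)) for row in rows
    )


def stepwise_to_csv(dec: StepwiseDecomposition, path) -> None:
    dec.to_frame().to_csv(path, index=False)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True))
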