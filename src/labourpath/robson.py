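"""Robson ten-group reporting and direct standardization across classes.

The Robson classification partitions an obstetric population into homogeneous
groups (by parity, previous caesarean, onset of labour, gestation,
presentation and plurality); the standard report derives, for each class, its
relative size, its caesarean rate, its contribution to the overall caesarean
rate, and its share of all caesareans.  Direct standardization re-weights
class-specific treatment ratios by a fixed reference class distribution so
that cohorts with different case mixes become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .measures import aggregate_ratio, overall_treatment_ratio
from .protocol import ROBSON_CLASSES, DegenerateCohortError, PathCountTable

__all__ = [
    "RobsonClassCounts",
    "robson_report",
    "standardized_ratio",
    "pooled_reference_weights",
]


@dataclass(frozen=True)
class RobsonClassCounts:
    """Women and caesarean counts for one Robson class."""

    label: str
    women: int
    caesareans: int

    def __post_init__(self):
        if self.label not in ROBSON_CLASSES:
            raise ValueError(
                f"unknown Robson class {self.label!r}; expected one of {ROBSON_CLASSES}"
            )
        if not (0 <= self.caesareans <= self.women):
            raise ValueError(
                f"class {self.label}: need 0 <= caesareans ({self.caesareans}) "
                f"<= women ({self.women})"
            )


def robson_report(classes: Sequence[RobsonClassCounts]) -> pd.DataFrame:
    """The standard Robson table with its four derived percentage columns.

    Columns: ``women``, ``caesareans``, ``relative_size_pct`` (women over the
    cohort total), ``cs_rate_pct`` (caesareans over the class's women; missing
    for empty classes), ``cs_contribution_pct`` (caesareans over the cohort
    total) and ``pct_of_all_cs`` (caesareans over all caesareans).  A
    ``Total`` row closes the table; its CS rate equals the overall caesarean
    rate, which also equals the sum of the per-class contributions.
    """
    if not classes:
        raise ValueError("need at least one Robson class")
    seen = [c.label for c in classes]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate Robson class labels: {seen}")
    total_women = sum(c.women for c in classes)
    total_cs = sum(c.caesareans for c in classes)
    if total_women <= 0:
        raise DegenerateCohortError("Robson report needs a positive total of women")

    rows = []
    for c in sorted(classes, key=lambda c: ROBSON_CLASSES.index(c.label)):
        rows.append(
            {
                "class": c.label,
                "women": c.women,
                "caesareans": c.caesareans,
                "relative_size_pct": 100 * c.women / total_women,
                "cs_rate_pct": (
                    100 * c.caesareans / c.women if c.women > 0 else float("nan")
                ),
                "cs_contribution_pct": 100 * c.caesareans / total_women,
                "pct_of_all_cs": (
                    100 * c.caesareans / total_cs if total_cs > 0 else float("nan")
                ),
            }
        )
    rows.append(
        {
            "class": "Total",
            "women": total_women,
            "caesareans": total_cs,
            "relative_size_pct": 100.0,
            "cs_rate_pct": 100 * total_cs / total_women,
            "cs_contribution_pct": 100 * total_cs / total_women,
            "pct_of_all_cs": 100.0 if total_cs > 0 else float("nan"),
        }
    )
    return pd.DataFrame(rows).set_index("class")


def pooled_reference_weights(
    *cohorts: Mapping[str, PathCountTable],
) -> dict[str, int]:
    """Default reference: the pooled class distribution of the given cohorts."""
    weights: dict[str, int] = {}
    for cohort in cohorts:
        for label, table in cohort.items():
            weights[label] = weights.get(label, 0) + table.N
    return weights


def standardized_ratio(
    cohort1: Mapping[str, PathCountTable],
    cohort2: Mapping[str, PathCountTable],
    reference_weights: Mapping[str, float] | None = None,
    functional: str | Sequence[str] = "H",
) -> tuple[float, float]:
    """Directly standardized treatment ratios for two cohorts.

    Each cohort's class-specific functional values (H for ``functional="H"``,
    otherwise the sum of the named type-specific ratios) are averaged with the
    common ``reference_weights`` (default: pooled class sizes), removing
    case-mix differences.  Classes carrying positive weight must be present
    and non-empty in both cohorts.
    """
    if reference_weights is None:
        reference_weights = pooled_reference_weights(cohort1, cohort2)
    weights = {k: float(w) for k, w in reference_weights.items()}
    if any(w < 0 for w in weights.values()):
        raise ValueError("reference weights must be nonnegative")
    total_w = sum(weights.values())
    if total_w <= 0:
        raise ValueError("reference weights must have a positive sum")

    def class_value(table: PathCountTable) -> Fraction:
        if functional == "H" or (
            not isinstance(functional, str)
            and tuple(functional) == table.protocol.labels
        ):
            return overall_treatment_ratio(table).H_exact
        if isinstance(functional, str):
            subset = tuple(p for p in functional.replace("+", " ").split() if p)
        else:
            subset = tuple(functional)
        return aggregate_ratio(table, subset)

    out = []
    for name, cohort in (("cohort 1", cohort1), ("cohort 2", cohort2)):
        acc = 0.0
        for label, w in weights.items():
            if w == 0:
                continue
            if label not in cohort:
                raise ValueError(f"{name} has no table for weighted class {label!r}")
            table = cohort[label]
            if table.N == 0:
                raise ValueError(f"{name}, class {label!r}: N = 0 with weight > 0")
            acc += w * float(class_value(table))
        out.append(acc / total_w)
    return out[0], out[1]
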