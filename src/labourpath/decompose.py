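"""Attributing inter-cohort differences in treatment ratios to components.

Two complementary decompositions of an observed difference ``H_2 − H_1``:

* **Multiplicative (treated proportion × intensity).**  Since ``H = S·H_T``,
  the relative difference splits exactly into the relative change in ``S``,
  the relative change in ``H_T`` and their product (the interaction).

* **Stepwise replacement of progression proportions.**  Writing the
  functional (H, a single type-specific ratio, or a sum of them) in terms of
  cohort-1 PPs and replacing them one at a time with cohort-2 values yields a
  sequence of intermediate values whose successive differences — the partial
  differences — sum exactly to the total difference, whatever the replacement
  order (a Kitagawa-style decomposition).  Contributions are conventionally
  rescaled so the first step reads ±100.

The replacement order matters for the size (not the sum) of the partial
differences; :func:`order_sensitivity` quantifies this by evaluating every
permutation, whose per-PP average is the Shapley attribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import ProgressionProportions, visit_probabilities
from .measures import form1_components, overall_treatment_ratio
from .protocol import PathCountTable

__all__ = [
    "Form1Decomposition",
    "StepwiseDecomposition",
    "form1_decompose",
    "stepwise_replacement",
    "order_sensitivity",
    "evaluate_functional",
]


@dataclass(frozen=True)
class Form1Decomposition:
    """Relative difference in H split into S-change, H_T-change, interaction."""

    rel_S: float
    rel_H_T: float
    interaction: float
    total: float  # (H2 - H1)/H1

    def as_dict(self) -> dict:
        return {
            "rel_S": self.rel_S,
            "rel_H_T": self.rel_H_T,
            "interaction": self.interaction,
            "total": self.total,
        }


def form1_decompose(
    table1: PathCountTable, table2: PathCountTable
) -> Form1Decomposition:
    """Decompose (H2−H1)/H1 = ΔS/S1 + ΔH_T/H_T1 + (ΔS/S1)(ΔH_T/H_T1)."""
    f1, f2 = form1_components(table1), form1_components(table2)
    if f1.H_T_exact is None:
        raise ValueError(
            "cohort 1 has no treated women (S = 0); relative changes undefined"
        )
    if f2.H_T_exact is None:
        raise ValueError("cohort 2 has no treated women (S = 0)")
    rel_S = f2.S_exact / f1.S_exact - 1
    rel_HT = f2.H_T_exact / f1.H_T_exact - 1
    h1 = overall_treatment_ratio(table1).H_exact
    h2 = overall_treatment_ratio(table2).H_exact
    total = h2 / h1 - 1
    assert abs(float(total - (rel_S + rel_HT + rel_S * rel_HT))) < 1e-12
    return Form1Decomposition(
        rel_S=float(rel_S),
        rel_H_T=float(rel_HT),
        interaction=float(rel_S * rel_HT),
        total=float(total),
    )


def _normalise_functional(
    functional: str | Sequence[str], protocol_labels: Sequence[str]
) -> tuple[str, tuple[str, ...]]:
    """Resolve a functional spec to (name, subset of intervention labels)."""
    if isinstance(functional, str):
        if functional == "H":
            return "H", tuple(protocol_labels)
        if functional in protocol_labels:
            return f"H_{functional}", (functional,)
        parts = [p for p in functional.replace("+", " ").split() if p]
        if parts and all(p in protocol_labels for p in parts):
            return "H_" + "+".join(parts), tuple(parts)
        raise ValueError(
            f"unknown functional {functional!r}; use 'H', an intervention label, "
            "or a '+'-joined subset of labels"
        )
    subset = tuple(functional)
    if not subset or any(l not in protocol_labels for l in subset):
        raise ValueError(f"functional subset {subset} not within {protocol_labels}")
    name = "H" if subset == tuple(protocol_labels) else "H_" + "+".join(subset)
    return name, subset


def evaluate_functional(
    pps: ProgressionProportions, functional: str | Sequence[str] = "H"
):
    """Evaluate H or a (sum of) type-specific ratio(s) at a PP set."""
    _, subset = _normalise_functional(functional, pps.protocol.labels)
    v = visit_probabilities(pps)
    return sum((v[l] for l in subset), Fraction(0))


@dataclass
class StepwiseDecomposition:
    """Result of the stepwise replacement of cohort-1 PPs by cohort-2 PPs.

    ``step_values[0]`` is the functional on cohort-1 PPs and
    ``step_values[k]`` on cohort-2 PPs; ``deltas[i]`` is the partial
    difference contributed by replacing ``order[i]``; ``contributions`` scale
    the deltas so the first is ±100 (missing when the first delta is zero).
    """

    functional: str
    order: tuple[tuple[str, str], ...]
    step_values: list[float]
    deltas: list[float]
    contributions: list[float] | None

    @property
    def total(self) -> float:
        return self.step_values[-1] - self.step_values[0]

    def to_frame(self) -> pd.DataFrame:
        labels = ["->".join(p) for p in self.order]
        return pd.DataFrame(
            {
                "replaced": labels,
                "value_after": self.step_values[1:],
                "partial_difference": self.deltas,
                "relative_contribution": (
                    self.contributions
                    if self.contributions is not None
                    else [math.nan] * len(self.deltas)
                ),
            }
        )

    def as_dict(self) -> dict:
        return {
            "functional": self.functional,
            "order": ["->".join(p) for p in self.order],
            "step_values": list(map(float, self.step_values)),
            "partial_differences": list(map(float, self.deltas)),
            "relative_contributions": (
                None
                if self.contributions is None
                else list(map(float, self.contributions))
            ),
        }


def _coerce_order(
    pps: ProgressionProportions,
    order: Sequence[tuple[str, str] | str] | None,
) -> tuple[tuple[str, str], ...]:
    pairs = pps.pairs()
    if order is None:
        return tuple(pairs)
    norm: list[tuple[str, str]] = []
    for item in order:
        if isinstance(item, str):
            if "->" in item:
                s, t = item.split("->")
            else:
                s, t = item[0], item[1:]
            norm.append((s, t))
        else:
            norm.append((item[0], item[1]))
    if sorted(norm) != sorted(pairs):
        raise ValueError(
            f"replacement order must be a permutation of {pairs}, got {norm}"
        )
    return tuple(norm)


def stepwise_replacement(
    pps1: ProgressionProportions,
    pps2: ProgressionProportions,
    functional: str | Sequence[str] = "H",
    order: Sequence[tuple[str, str] | str] | None = None,
) -> StepwiseDecomposition:
    """Replace cohort-1 PPs one at a time with cohort-2 values.

    The default order is the natural one — replace first the PPs leading to
    less invasive treatments: source state ascending, then target ascending
    ((O,A), (O,V), (O,C), (A,V), (A,C), (V,C) for three interventions).
    """
    if pps1.protocol.labels != pps2.protocol.labels:
        raise ValueError("both PP sets must be defined on the same protocol")
    name, _ = _normalise_functional(functional, pps1.protocol.labels)
    order_t = _coerce_order(pps1, order)

    current = pps1
    values = [evaluate_functional(current, functional)]
    for (s, t) in order_t:
        current = current.replace(s, t, pps2.get(s, t))
        values.append(evaluate_functional(current, functional))
    deltas = [values[i + 1] - values[i] for i in range(len(order_t))]

    if deltas and deltas[0] != 0:
        scale = abs(deltas[0])
        contributions = [float(100 * d / scale) for d in deltas]
    else:
        contributions = None
    return StepwiseDecomposition(
        functional=name,
        order=order_t,
        step_values=[float(v) for v in values],
        deltas=[float(d) for d in deltas],
        contributions=contributions,
    )


def order_sensitivity(
    pps1: ProgressionProportions,
    pps2: ProgressionProportions,
    functional: str | Sequence[str] = "H",
    max_orders: int = 5040,
    sample: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Partial differences for every replacement order (or a random sample).

    Returns a tidy frame with one row per (order, PP) giving the partial
    difference attributed to that PP under that order.  The per-PP mean over
    all k! orders is the Shapley attribution.  With k! > ``max_orders`` a
    ``sample`` size must be given (drawn with the seeded generator).
    """
    pairs = pps1.pairs()
    k = len(pairs)
    n_orders = math.factorial(k)
    if n_orders > max_orders and sample is None:
        raise ValueError(
            f"{k}! = {n_orders} orders exceed the cap ({max_orders}); "
            "pass a sample size"
        )
    if sample is not None and n_orders > max_orders:
        rng = np.random.default_rng(seed)
        orders = [tuple(rng.permutation(k)) for _ in range(sample)]
        orders = [tuple(pairs[i] for i in idx) for idx in orders]
    else:
        orders = list(permutations(pairs))

    rows = []
    for oi, order in enumerate(orders):
        dec = stepwise_replacement(pps1, pps2, functional, order)
        for pair, delta in zip(order, dec.deltas):
            rows.append(
                {"order": oi, "pp": "->".join(pair), "partial_difference": delta}
            )
    return pd.DataFrame(rows)


def order_sensitivity_summary(detail: pd.DataFrame) -> pd.DataFrame:
    """Per-PP min/mean/max of the partial differences across orders."""
    g = detail.groupby("pp")["partial_difference"]
    out = g.agg(["min", "mean", "max"]).reset_index()
    out.columns = ["pp", "min", "shapley_mean", "max"]
    return out
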