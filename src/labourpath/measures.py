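"""Intervention-intensity measures computed from a path-count table.

The overall treatment ratio (OTR) ``H = E/N`` — total treatments over total
women — admits several equivalent representations, each exposing a different
facet of intervention intensity:

* treated proportion × mean treatments among the treated (``H = S·H_T``),
* sum of type-specific treatment ratios (``H = H_A + H_V + H_C``),
* mean of the distribution of the number of treatments (``H = Σ i·f_i``),
* mean number of treatments over the path distribution (``H = Σ (x+y+z)·f(path)``),
* a polynomial in the progression proportions of the Markov representation
  (see :mod:`labourpath.markov`).

All ratios are computed in exact rational arithmetic (``fractions.Fraction``)
and exposed as floats; rounding happens only in rendered reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Sequence

from .protocol import PathCountTable, ProtocolError

__all__ = [
    "MeasureSet",
    "Form1Components",
    "TypeSpecificRatios",
    "TreatmentCountDistribution",
    "overall_treatment_ratio",
    "form1_components",
    "type_specific_ratios",
    "treatment_count_distribution",
    "aggregate_ratio",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used in printed reports)."""
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP) if x >= 0 else \
        -((-Decimal(repr(float(x)))).quantize(q, rounding=ROUND_HALF_UP))
    return float(d)


@dataclass(frozen=True)
class MeasureSet:
    """Total treatments E, overall treatment ratio H and iatrogenic index."""

    N: int
    E: int
    H_exact: Fraction
    ILI_exact: Fraction

    @property
    def H(self) -> float:
        """Average treatments per woman, in [0, n]."""
        return float(self.H_exact)

    @property
    def ILI(self) -> float:
        """Iatrogenic labour index H/n, normalised to [0, 1]."""
        return float(self.ILI_exact)


@dataclass(frozen=True)
class Form1Components:
    """Treated proportion S and mean treatments among the treated H_T."""

    N0: int
    S_exact: Fraction
    H_T_exact: Fraction | None  # None when no woman was treated

    @property
    def S(self) -> float:
        return float(self.S_exact)

    @property
    def H_T(self) -> float | None:
        return None if self.H_T_exact is None else float(self.H_T_exact)


@dataclass(frozen=True)
class TypeSpecificRatios:
    """Per-intervention treatment counts E_j and ratios H_j = E_j/N."""

    labels: tuple[str, ...]
    E_j: dict[str, int]
    H_j_exact: dict[str, Fraction]

    @property
    def H_j(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.H_j_exact.items()}


@dataclass(frozen=True)
class TreatmentCountDistribution:
    """Distribution of the number of treatments and of the paths themselves."""

    N_i: dict[int, int]
    f_i_exact: dict[int, Fraction]
    f_path_exact: dict[tuple[int, ...], Fraction]

    @property
    def f_i(self) -> dict[int, float]:
        return {k: float(v) for k, v in self.f_i_exact.items()}

    @property
    def f_path(self) -> dict[tuple[int, ...], float]:
        return {k: float(v) for k, v in self.f_path_exact.items()}

    @property
    def mean_exact(self) -> Fraction:
        return sum((i * f for i, f in self.f_i_exact.items()), Fraction(0))


def overall_treatment_ratio(table: PathCountTable) -> MeasureSet:
    """Compute E, H = E/N and the iatrogenic labour index ILI = H/n."""
    table.require_nonempty()
    E = sum(sum(path) * c for path, c in table.counts.items())
    H = Fraction(E, table.N)
    return MeasureSet(N=table.N, E=E, H_exact=H, ILI_exact=H / table.protocol.n)


def form1_components(table: PathCountTable) -> Form1Components:
    """Split H into treated proportion S and intensity H_T among the treated."""
    table.require_nonempty()
    N = table.N
    N0 = table.count((0,) * table.protocol.n)
    S = Fraction(N - N0, N)
    if N0 == N:
        return Form1Components(N0=N0, S_exact=S, H_T_exact=None)
    E = overall_treatment_ratio(table).E
    return Form1Components(N0=N0, S_exact=S, H_T_exact=Fraction(E, N - N0))


def type_specific_ratios(table: PathCountTable) -> TypeSpecificRatios:
    """E_j and H_j = E_j/N for each intervention type; Σ_j H_j = H exactly."""
    table.require_nonempty()
    labels = table.protocol.labels
    E_j = {l: 0 for l in labels}
    for path, c in table.counts.items():
        for j, flag in enumerate(path):
            if flag:
                E_j[labels[j]] += c
    H_j = {l: Fraction(e, table.N) for l, e in E_j.items()}
    return TypeSpecificRatios(labels=labels, E_j=E_j, H_j_exact=H_j)


def treatment_count_distribution(table: PathCountTable) -> TreatmentCountDistribution:
    """Distribution of treatment counts (f_i) and of paths (f(x,y,z))."""
    table.require_nonempty()
    n, N = table.protocol.n, table.N
    N_i = {i: 0 for i in range(n + 1)}
    for path, c in table.counts.items():
        N_i[sum(path)] += c
    f_i = {i: Fraction(c, N) for i, c in N_i.items()}
    f_path = {tuple(p): Fraction(table.count(p), N) for p in table.paths()}
    return TreatmentCountDistribution(N_i=N_i, f_i_exact=f_i, f_path_exact=f_path)


def aggregate_ratio(table: PathCountTable, subset: Sequence[str]) -> Fraction:
    """Sum of type-specific ratios over a subset of interventions.

    With ``subset = ("V", "C")`` this is the operative-delivery intensity
    ``H_V + H_C``; with all labels it equals H.
    """
    strs = type_specific_ratios(table)
    for label in subset:
        if label not in strs.H_j_exact:
            raise ProtocolError(
                f"unknown intervention {label!r}; protocol is {table.protocol.labels}"
            )
    return sum((strs.H_j_exact[l] for l in subset), Fraction(0))


def measures_report(table: PathCountTable) -> dict:
    """JSON-serialisable summary of every measure for one cohort."""
    ms = overall_treatment_ratio(table)
    f1 = form1_components(table)
    strs = type_specific_ratios(table)
    dist = treatment_count_distribution(table)
    return {
        "N": ms.N,
        "E": ms.E,
        "H": ms.H,
        "ILI": ms.ILI,
        "S": f1.S,
        "H_T": f1.H_T,
        "per_intervention": {
            l: {"E": strs.E_j[l], "H": float(strs.H_j_exact[l])} for l in strs.labels
        },
        "f_i": {str(i): float(f) for i, f in dist.f_i_exact.items()},
        "f_path": {
            "".join(map(str, p)): float(f) for p, f in dist.f_path_exact.items()
        },
    }
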