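"""Model/Results objects tying the framework together.

:class:`CohortPathwayModel` wraps one cohort's path-count table; ``fit()``
estimates every measure and the Markov progression proportions, returning a
:class:`CohortPathwayResults` with a ``summary()`` table, diagnostics (the
Markov-property tests, the model-implied path distribution) and a
``simulate()`` method for parametric resimulation.

:class:`PathwayComparison` takes two cohorts; ``fit()`` runs the full
comparison: the multiplicative split of the relative OTR difference, the
stepwise-replacement decompositions for the requested functionals, the
chi-square comparison of path distributions and per-intervention proportion
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import measures as _measures
from .decompose import (
    Form1Decomposition,
    StepwiseDecomposition,
    form1_decompose,
    stepwise_replacement,
)
from .markov import (
    MarkovTestResult,
    ProgressionProportions,
    estimate_progression_proportions,
    markov_property_test,
    otr_from_pps,
    reconstruct_path_distribution,
    visit_probabilities,
)
from .measures import round_half_away
from .protocol import (
    DEFAULT_PROTOCOL,
    InterventionProtocol,
    PathCountTable,
    path_table_from_records,
)
from .stats import (
    PathComparisonResult,
    ProportionTestResult,
    compare_path_distributions,
    compare_proportions,
)

__all__ = [
    "CohortPathwayModel",
    "CohortPathwayResults",
    "PathwayComparison",
    "PathwayComparisonResults",
]


class CohortPathwayModel:
    """Staged-intervention pathway model for a single cohort."""

    def __init__(self, table: PathCountTable, name: str | None = None):
        self.table = table
        self.name = name or table.stratum or "cohort"

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        protocol: InterventionProtocol = DEFAULT_PROTOCOL,
        name: str | None = None,
    ) -> "CohortPathwayModel":
        """Build from per-woman 0/1 intervention records."""
        return cls(path_table_from_records(records, protocol), name=name)

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[int, ...], int],
        protocol: InterventionProtocol = DEFAULT_PROTOCOL,
        name: str | None = None,
    ) -> "CohortPathwayModel":
        return cls(PathCountTable(protocol, dict(counts)), name=name)

    def fit(self, markov_test: bool = True) -> "CohortPathwayResults":
        """Estimate all measures and progression proportions."""
        t = self.table
        res = CohortPathwayResults(
            model=self,
            measures=_measures.overall_treatment_ratio(t),
            form1=_measures.form1_components(t),
            strs=_measures.type_specific_ratios(t),
            distribution=_measures.treatment_count_distribution(t),
            pps=estimate_progression_proportions(t),
            markov_tests=(
                markov_property_test(t) if markov_test and t.protocol.n >= 2 else []
            ),
        )
        return res


@dataclass
class CohortPathwayResults:
    """Fitted measures, progression proportions and diagnostics."""

    model: CohortPathwayModel
    measures: _measures.MeasureSet
    form1: _measures.Form1Components
    strs: _measures.TypeSpecificRatios
    distribution: _measures.TreatmentCountDistribution
    pps: ProgressionProportions
    markov_tests: list[MarkovTestResult] = field(default_factory=list)

    @property
    def reconstructed_path_distribution(self):
        """Path distribution implied by the fitted Markov chain."""
        return reconstruct_path_distribution(self.pps)

    def simulate(self, n_women: int | None = None, seed: int = 0) -> PathCountTable:
        """Resimulate a cohort from the fitted progression proportions."""
        from .simulate import SimulationConfig, simulate_cohort

        n = self.measures.N if n_women is None else n_women
        return simulate_cohort(SimulationConfig(self.pps, n, seed))

    def to_report_dict(self) -> dict:
        report = _measures.measures_report(self.model.table)
        report["cohort"] = self.model.name
        report["progression_proportions"] = {
            "->".join(k): float(v) for k, v in sorted(self.pps.pp.items())
        }
        report["markov_tests"] = [
            {
                "state": r.state,
                "target": r.target,
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "note": r.note,
            }
            for r in self.markov_tests
        ]
        return report

    def summary(self) -> str:
        """Plain-text summary of the fitted cohort."""
        m, f1, n = self.measures, self.form1, self.model.table.protocol.n
        lines = [
            f"Staged-intervention pathway model — {self.model.name}",
            "=" * 58,
            f"Women (N):                {m.N}",
            f"Treatments (E):           {m.E}",
            f"Overall treatment ratio:  {m.H:.4f}  "
            f"({round_half_away(100 * m.H, 1):.1f} per 100 women)",
            f"Iatrogenic labour index:  {m.ILI:.4f}  (H/n, n={n})",
            f"Treated proportion S:     {f1.S:.4f}",
            f"Intensity among treated:  "
            + ("-" if f1.H_T is None else f"{f1.H_T:.4f}"),
            "",
            "Type-specific treatment ratios:",
        ]
        for label in self.strs.labels:
            lines.append(
                f"  H_{label}: {float(self.strs.H_j_exact[label]):.4f}"
                f"  (E_{label}={self.strs.E_j[label]})"
            )
        lines.append("")
        lines.append("Progression proportions (history-pooled MLE):")
        for (s, t), v in sorted(self.pps.pp.items()):
            d = self.pps.denominators.get(s, 0)
            lines.append(f"  p_{s}{t}: {float(v):.4f}  (denominator {d})")
        if self.pps.undefined:
            und = ", ".join("->".join(p) for p in sorted(self.pps.undefined))
            lines.append(f"  undefined (state unreached): {und}")
        if self.markov_tests:
            lines.append("")
            lines.append("Markov-property tests (history homogeneity):")
            for r in self.markov_tests:
                if r.method == "skipped":
                    lines.append(f"  state {r.state}: skipped — {r.note}")
                else:
                    lines.append(
                        f"  {r.state}->{r.target}: p={r.p_value:.4f} ({r.method})"
                    )
        return "\n".join(lines)


class PathwayComparison:
    """Two-cohort comparison of intervention intensity."""

    def __init__(
        self,
        cohort1: CohortPathwayModel | PathCountTable,
        cohort2: CohortPathwayModel | PathCountTable,
    ):
        def as_model(c, default):
            if isinstance(c, PathCountTable):
                return CohortPathwayModel(c, name=c.stratum or default)
            return c

        self.model1 = as_model(cohort1, "cohort 1")
        self.model2 = as_model(cohort2, "cohort 2")
        if self.model1.table.protocol.labels != self.model2.table.protocol.labels:
            raise ValueError("cohorts must share a protocol")

    def fit(
        self,
        functionals: Sequence[str | Sequence[str]] = ("H",),
        order: Sequence | None = None,
        min_expected: float = 5.0,
    ) -> "PathwayComparisonResults":
        r1 = self.model1.fit(markov_test=False)
        r2 = self.model2.fit(markov_test=False)
        stepwise = {}
        for fn in functionals:
            dec = stepwise_replacement(r1.pps, r2.pps, fn, order)
            stepwise[dec.functional] = dec
        prop_tests = {}
        for label in self.model1.table.protocol.labels:
            prop_tests[label] = compare_proportions(
                r1.strs.E_j[label], r1.measures.N,
                r2.strs.E_j[label], r2.measures.N,
            )
        return PathwayComparisonResults(
            comparison=self,
            results1=r1,
            results2=r2,
            form1_decomposition=form1_decompose(self.model1.table, self.model2.table),
            stepwise=stepwise,
            path_test=compare_path_distributions(
                self.model1.table, self.model2.table, min_expected=min_expected
            ),
            proportion_tests=prop_tests,
        )


@dataclass
class PathwayComparisonResults:
    """All components of a two-cohort comparison."""

    comparison: PathwayComparison
    results1: CohortPathwayResults
    results2: CohortPathwayResults
    form1_decomposition: Form1Decomposition
    stepwise: dict[str, StepwiseDecomposition]
    path_test: PathComparisonResult
    proportion_tests: dict[str, ProportionTestResult]

    @property
    def relative_difference(self) -> float:
        """(H2 − H1)/H1."""
        return self.form1_decomposition.total

    def to_report_dict(self) -> dict:
        return {
            "cohort1": self.results1.to_report_dict(),
            "cohort2": self.results2.to_report_dict(),
            "form1_decomposition": self.form1_decomposition.as_dict(),
            "stepwise": {k: v.as_dict() for k, v in self.stepwise.items()},
            "path_distribution_test": self.path_test.as_dict(),
            "proportion_tests": {
                k: {"statistic": v.statistic, "p_value": v.p_value, "note": v.note}
                for k, v in self.proportion_tests.items()
            },
        }

    def summary(self) -> str:
        from .io import render_stepwise_text

        m1, m2 = self.results1.measures, self.results2.measures
        d = self.form1_decomposition
        lines = [
            f"Pathway comparison: {self.comparison.model1.name} vs "
            f"{self.comparison.model2.name}",
            "=" * 62,
            f"H1 = {m1.H:.4f}  ({round_half_away(100 * m1.H, 1):.1f}/100 women)   "
            f"H2 = {m2.H:.4f}  ({round_half_away(100 * m2.H, 1):.1f}/100 women)",
            f"Relative difference (H2-H1)/H1: {100 * d.total:+.1f}%",
            "",
            "Multiplicative split of the relative difference:",
            f"  treated proportion S:     {100 * d.rel_S:+.2f}%",
            f"  intensity among treated:  {100 * d.rel_H_T:+.2f}%",
            f"  interaction:              {100 * d.interaction:+.2f}%",
            "",
            f"Path-distribution test: chi2 = {self.path_test.statistic:.2f}, "
            f"df = {self.path_test.df}, p = {self.path_test.p_value:.3g}",
        ]
        for label, t in self.proportion_tests.items():
            lines.append(
                f"  H_{label} proportions: chi2 = {t.statistic:.2f}, "
                f"p = {t.p_value:.3g}"
            )
        for name, dec in self.stepwise.items():
            lines.append("")
            lines.append(f"Stepwise replacement — functional {name}:")
            lines.append(render_stepwise_text(dec))
        return "\n".join(lines)
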