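"""Markov (compartmental) representation of intervention pathways.

States are labour onset ``O``, one state per intervention, and birth ``B``
(absorbing).  A *progression proportion* (PP) ``p_{s,t}`` is the proportion of
women in state ``s`` whose next treatment is ``t``; the remainder
``1 - Σ_t p_{s,t}`` exits directly to birth.  Under the Markov hypothesis the
decision to progress depends only on the current state, not on the route by
which it was reached — a testable assumption (see
:func:`markov_property_test`).

The type-specific ratios are visit probabilities of the chain and satisfy the
forward recursion ``v_j = p_{O,j} + Σ_{i<j} v_i·p_{i,j}``; for three
interventions this reproduces the closed forms
``H_A = p_OA``, ``H_V = p_OV + p_OA·p_AV`` and
``H_C = p_OC + p_OA·p_AC + p_OV·p_VC + p_OA·p_AV·p_VC``.
When PPs are estimated from a table by the history-pooled maximum-likelihood
estimator, ``N·v_j`` equals the integer treatment count ``E_j`` exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

from scipy import stats as sps

from .protocol import DEFAULT_PROTOCOL, InterventionProtocol, PathCountTable

__all__ = [
    "ProgressionProportions",
    "MarkovTestResult",
    "estimate_progression_proportions",
    "visit_probabilities",
    "otr_from_pps",
    "reconstruct_path_distribution",
    "markov_property_test",
]

ONSET = "O"


class UndefinedProgressionWarning(UserWarning):
    """An unreached state made a progression proportion undefined."""


@dataclass
class ProgressionProportions:
    """Forward transition proportions between intervention states.

    ``pp`` maps ``(source, target)`` label pairs — source ``"O"`` or an
    intervention, target a strictly later intervention — to proportions in
    [0, 1].  ``denominators`` records how many women reached each source
    state; pairs whose source was never reached are listed in ``undefined``
    and treated as zero (with a warning) by downstream functionals.
    """

    protocol: InterventionProtocol
    pp: dict[tuple[str, str], Fraction | float] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)
    undefined: set[tuple[str, str]] = field(default_factory=set)
    #: stepwise-replacement intermediates mix two cohorts' PPs and are formal
    #: polynomial arguments, not a realisable chain: they skip the row-sum check
    check_row_sums: bool = True

    def __post_init__(self):
        states = self.states
        for (s, t), v in self.pp.items():
            if s not in states[:-1]:
                raise ValueError(f"unknown source state {s!r}")
            si = states.index(s)
            if t not in self.protocol.labels:
                raise ValueError(f"unknown target state {t!r}")
            ti = states.index(t)
            if ti <= si:
                raise ValueError(f"transition {s}->{t} is not forward")
            if not (0 <= v <= 1):
                raise ValueError(f"p_{s}{t} = {float(v)} outside [0, 1]")
        if self.check_row_sums:
            for s in states[:-1]:
                total = sum(
                    (self.pp.get((s, t), 0) for t in self._targets(s)), Fraction(0)
                )
                if total > 1 + 1e-12:
                    raise ValueError(
                        f"outgoing proportions from {s} sum to {float(total)} > 1"
                    )

    @property
    def states(self) -> list[str]:
        return [ONSET, *self.protocol.labels]

    def _targets(self, source: str) -> list[str]:
        i = self.states.index(source)
        return list(self.states[i + 1:])

    def pairs(self) -> list[tuple[str, str]]:
        """All forward (source, target) pairs in natural replacement order:
        source state ascending, then target ascending."""
        out = []
        for i, s in enumerate(self.states[:-1]):
            for t in self.states[i + 1:]:
                out.append((s, t))
        return out

    def get(self, source: str, target: str):
        """Proportion for a pair; undefined entries come back as 0 with a warning."""
        if (source, target) in self.undefined:
            warnings.warn(
                f"p_{source}{target} is undefined (no woman reached {source}); "
                "treated as 0",
                UndefinedProgressionWarning,
                stacklevel=2,
            )
            return Fraction(0)
        return self.pp.get((source, target), Fraction(0))

    def replace(self, source: str, target: str, value) -> "ProgressionProportions":
        """A copy with one entry replaced (used by stepwise decomposition)."""
        new = dict(self.pp)
        new[(source, target)] = value
        return ProgressionProportions(
            self.protocol, new, dict(self.denominators),
            set(self.undefined) - {(source, target)},
            check_row_sums=False,
        )

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "states": self.states,
                "pp": {f"{s}->{t}": float(v) for (s, t), v in sorted(self.pp.items())},
                "denominators": self.denominators,
                "undefined": sorted(f"{s}->{t}" for s, t in self.undefined),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProgressionProportions":
        obj = json.loads(text)
        protocol = InterventionProtocol(obj["states"][1:])
        pp = {}
        for key, v in obj["pp"].items():
            s, t = key.split("->")
            pp[(s, t)] = float(v)
        undefined = set()
        for key in obj.get("undefined", []):
            s, t = key.split("->")
            undefined.add((s, t))
        return cls(protocol, pp, dict(obj.get("denominators", {})), undefined)


def _visited(path: Sequence[int], labels: Sequence[str]) -> list[str]:
    return [labels[i] for i, f in enumerate(path) if f]


def estimate_progression_proportions(table: PathCountTable) -> ProgressionProportions:
    """History-pooled maximum-likelihood estimate of the PPs.

    A woman reaches ``O`` always and reaches an intervention state iff her
    flag for it is 1; her transition from state ``s`` goes to the next 1-flag
    after ``s`` in protocol order, or to birth if none.  All arrival histories
    are pooled (e.g. ``p_VC`` counts women who reached V directly and via A
    together) — the choice under which ``N·v_j = E_j`` holds exactly.
    """
    table.require_nonempty()
    labels = table.protocol.labels
    numer: dict[tuple[str, str], int] = {}
    denom: dict[str, int] = {ONSET: table.N}
    denom.update({l: 0 for l in labels})
    for path, c in table.counts.items():
        visited = _visited(path, labels)
        prev = ONSET
        for t in visited:
            numer[(prev, t)] = numer.get((prev, t), 0) + c
            denom[t] += c
            prev = t

    pps = ProgressionProportions(table.protocol, {}, denom)
    for i, s in enumerate(pps.states[:-1]):
        for t in pps.states[i + 1:]:
            d = denom[s]
            if d == 0:
                pps.undefined.add((s, t))
            else:
                pps.pp[(s, t)] = Fraction(numer.get((s, t), 0), d)
    return pps


def visit_probabilities(pps: ProgressionProportions) -> dict[str, Fraction | float]:
    """Probability of visiting each intervention state, by forward recursion.

    ``v_j = p_{O,j} + Σ_{i<j} v_i·p_{i,j}``; exact when the PPs are exact.
    """
    v: dict[str, Fraction | float] = {}
    for j in pps.protocol.labels:
        total = pps.get(ONSET, j)
        for i in pps.protocol.labels:
            if i == j:
                break
            total = total + v[i] * pps.get(i, j)
        v[j] = total
    return v


def otr_from_pps(pps: ProgressionProportions):
    """Overall treatment ratio as a functional of the PPs: H = Σ_j v_j."""
    return sum(visit_probabilities(pps).values())


def reconstruct_path_distribution(
    pps: ProgressionProportions,
) -> dict[tuple[int, ...], Fraction | float]:
    """Path distribution implied by the Markov chain.

    Each path's probability is the product of its transition proportions times
    the exit probability (to birth) from its last visited state.  Sums to 1.
    Equals the empirical path frequencies iff history-specific progression
    proportions coincide with the pooled ones (the Markov property).
    """
    labels = pps.protocol.labels
    out: dict[tuple[int, ...], Fraction | float] = {}
    from .protocol import enumerate_paths

    for path in enumerate_paths(pps.protocol):
        flags = tuple(path.flags)
        visited = _visited(flags, labels)
        prob: Fraction | float = Fraction(1)
        prev = ONSET
        for t in visited:
            prob = prob * pps.get(prev, t)
            prev = t
        exit_prob = Fraction(1) - sum(
            (pps.get(prev, t) for t in pps._targets(prev)), Fraction(0)
        )
        out[flags] = prob * exit_prob
    return out


@dataclass(frozen=True)
class MarkovTestResult:
    """One history-homogeneity test at a (state, target) pair."""

    state: str
    target: str
    histories: tuple[tuple[str, ...], ...]  # earlier treatments received
    progressed: tuple[int, ...]  # per history: # whose next treatment is target
    at_risk: tuple[int, ...]  # per history: # who reached the state
    statistic: float | None
    p_value: float | None
    method: str
    note: str | None = None

    @property
    def contingency(self) -> list[list[int]]:
        return [
            list(self.progressed),
            [n - k for n, k in zip(self.at_risk, self.progressed)],
        ]


def markov_property_test(
    table: PathCountTable,
    bonferroni: bool = False,
) -> list[MarkovTestResult]:
    """Test that progression is history-independent at every testable state.

    For each intervention state ``s`` reachable by at least two distinct
    histories (subsets of earlier treatments) and each later target ``t``, the
    women who reached ``s`` are cross-classified as history × (next treatment
    is ``t``) and tested for homogeneity: Fisher's exact test when two
    histories are observed, the chi-square test of homogeneity otherwise
    (noted in the result).  No multiplicity correction by default;
    ``bonferroni=True`` multiplies p-values by the number of tests performed.
    """
    if table.protocol.n < 2:
        raise ValueError("the Markov property needs at least two interventions")
    labels = table.protocol.labels
    results: list[MarkovTestResult] = []

    for si, s in enumerate(labels):
        if si == 0:
            continue  # first intervention has a single (empty) history
        later = labels[si + 1:]
        # women reaching s, grouped by which earlier treatments they received
        groups: dict[tuple[str, ...], dict[tuple[int, ...], int]] = {}
        for path, c in table.counts.items():
            if path[si] != 1 or c == 0:
                continue
            hist = tuple(labels[i] for i in range(si) if path[i])
            groups.setdefault(hist, {})
            groups[hist][path] = groups[hist].get(path, 0) + c
        if len(groups) < 2:
            results.append(
                MarkovTestResult(
                    state=s, target="|".join(later) or "-", histories=tuple(groups),
                    progressed=(), at_risk=(), statistic=None, p_value=None,
                    method="skipped",
                    note=f"state {s} observed under {len(groups)} history; "
                    "need at least 2",
                )
            )
            continue
        histories = tuple(sorted(groups))
        for t in later:
            ti = labels.index(t)
            progressed, at_risk = [], []
            for hist in histories:
                sub = groups[hist]
                n = sum(sub.values())
                # next treatment after s is t: flags between s and t all zero
                k = sum(
                    c for p, c in sub.items()
                    if p[ti] == 1 and all(p[j] == 0 for j in range(si + 1, ti))
                )
                progressed.append(k)
                at_risk.append(n)
            tbl = [progressed, [n - k for n, k in zip(at_risk, progressed)]]
            if sum(progressed) in (0, sum(at_risk)):
                stat, p, method, note = 0.0, 1.0, "degenerate", (
                    f"progression to {t} from {s} is constant across histories"
                )
            elif len(histories) == 2:
                stat, p = sps.fisher_exact(tbl, alternative="two-sided")
                method, note = "fisher_exact", None
            else:
                res = sps.chi2_contingency(tbl, correction=False)
                stat, p = float(res.statistic), float(res.pvalue)
                method = "chi2_homogeneity"
                note = "more than two histories; exact test unavailable"
            results.append(
                MarkovTestResult(
                    state=s, target=t, histories=histories,
                    progressed=tuple(progressed), at_risk=tuple(at_risk),
                    statistic=float(stat), p_value=float(p), method=method, note=note,
                )
            )

    if bonferroni:
        m = sum(1 for r in results if r.p_value is not None and r.method != "skipped")
        adjusted = []
        for r in results:
            if r.p_value is not None and r.method != "skipped":
                r = MarkovTestResult(
                    r.state, r.target, r.histories, r.progressed, r.at_risk,
                    r.statistic, min(1.0, r.p_value * m), r.method,
                    (r.note or "") + f" [Bonferroni x{m}]",
                )
            adjusted.append(r)
        results = adjusted
    return results
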