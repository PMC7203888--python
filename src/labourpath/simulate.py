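"""Seeded cohort simulation under the sequential-intervention Markov model.

Each simulated woman starts at labour onset and, at every state she visits,
either progresses to one of the later interventions (with the configured
progression proportions) or exits to birth.  Optional *history modifiers*
deliberately break the Markov property: they adjust a transition's
probability, on the odds scale, for women whose earlier-treatment history
matches a condition — the controlled violation used to study the power of the
Markov-property test.

Sampling uses one uniform draw per state visit, in protocol order, from a
single seeded generator, so identical configurations yield bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import ONSET, ProgressionProportions, estimate_progression_proportions
from .protocol import DEFAULT_PROTOCOL, InterventionProtocol, PathCountTable

__all__ = [
    "HistoryModifier",
    "SimulationConfig",
    "simulate_cohort",
    "recovery_experiment",
]


@dataclass(frozen=True)
class HistoryModifier:
    """Odds-scale adjustment of one transition for a matching history.

    For women at ``source`` whose earlier flags match ``requires`` (a mapping
    intervention → 0/1), the probability of moving to ``target`` is replaced
    by ``odds*m / (1 + odds*m)`` where ``odds = p/(1-p)`` and ``m`` is
    ``odds_multiplier``; the result is clipped to [0, 1] (p = 1 maps to 1).
    """

    source: str
    target: str
    requires: Mapping[str, int]
    odds_multiplier: float

    def applies(self, flags_row: np.ndarray, labels: Sequence[str]) -> np.ndarray:
        mask = np.ones(flags_row.shape[0], dtype=bool)
        for lab, val in self.requires.items():
            mask &= flags_row[:, labels.index(lab)] == int(val)
        return mask

    def adjust(self, p: float) -> float:
        if self.odds_multiplier < 0:
            raise ValueError("odds multiplier must be nonnegative")
        if p >= 1.0:
            return 1.0
        odds = p / (1.0 - p) * self.odds_multiplier
        return float(np.clip(odds / (1.0 + odds), 0.0, 1.0))


@dataclass
class SimulationConfig:
    """Generative model for one simulated cohort."""

    pps: ProgressionProportions
    n_women: int
    seed: int
    modifiers: tuple[HistoryModifier, ...] = ()

    def __post_init__(self):
        if self.n_women < 0:
            raise ValueError("n_women must be nonnegative")
        self.modifiers = tuple(self.modifiers)
        labels = self.pps.protocol.labels
        for m in self.modifiers:
            if m.source not in labels or m.target not in labels:
                raise ValueError(f"modifier {m} names states outside {labels}")
            if labels.index(m.source) >= labels.index(m.target):
                raise ValueError(f"modifier {m} is not a forward transition")
        self._validate_probabilities()

    def _validate_probabilities(self):
        labels = self.pps.protocol.labels
        states = [ONSET, *labels]
        for si, s in enumerate(states[:-1]):
            base = [float(self.pps.pp.get((s, t), 0.0)) for t in states[si + 1:]]
            if any(not (0 <= p <= 1) for p in base):
                raise ValueError(f"invalid base probabilities out of state {s}")
            if sum(base) > 1 + 1e-12:
                raise ValueError(
                    f"outgoing probabilities from {s} sum to {sum(base):.6f} > 1"
                )
            # worst-case check with every matching modifier applied
            if s == ONSET:
                continue
            for combo in self._modifier_extremes(s, states[si + 1:], base):
                if sum(combo) > 1 + 1e-9:
                    raise ValueError(
                        f"history modifiers push outgoing probabilities from {s} "
                        f"above 1 ({sum(combo):.6f})"
                    )

    def _modifier_extremes(self, source, targets, base):
        adjusted = list(base)
        for m in self.modifiers:
            if m.source != source:
                continue
            j = targets.index(m.target)
            adjusted[j] = max(adjusted[j], m.adjust(base[j]))
        yield adjusted

    @classmethod
    def from_json_dict(cls, obj: dict) -> "SimulationConfig":
        protocol = InterventionProtocol(tuple(obj.get("protocol", ("A", "V", "C"))))
        pp = {}
        for key, v in obj["pp"].items():
            s, t = key.split("->")
            pp[(s, t)] = float(v)
        pps = ProgressionProportions(protocol, pp, {})
        mods = tuple(
            HistoryModifier(
                m["source"], m["target"], dict(m["requires"]),
                float(m["odds_multiplier"]),
            )
            for m in obj.get("modifiers", ())
        )
        return cls(pps=pps, n_women=int(obj["n_women"]), seed=int(obj["seed"]),
                   modifiers=mods)


def simulate_cohort(config: SimulationConfig) -> PathCountTable:
    """Sample a cohort and return its aggregated path-count table."""
    protocol = config.pps.protocol
    labels = list(protocol.labels)
    n, N = protocol.n, config.n_women
    rng = np.random.default_rng(config.seed)

    flags = np.zeros((N, n), dtype=np.int8)
    # state of each woman: -1 = onset, j = at intervention j, n = gave birth
    state = np.full(N, -1, dtype=np.int64)

    for si in range(-1, n - 1):  # visit states in protocol order; last has no exits
        at = np.nonzero(state == si)[0]
        if at.size == 0:
            continue  # no visits to this state, so no draws for it
        source = ONSET if si == -1 else labels[si]
        targets = labels[si + 1:]
        base = np.array(
            [float(config.pps.pp.get((source, t), 0.0)) for t in targets]
        )
        probs = np.tile(base, (at.size, 1))
        if si >= 0:
            for m in config.modifiers:
                if m.source != source:
                    continue
                mask = m.applies(flags[at], labels)
                j = targets.index(m.target)
                probs[mask, j] = m.adjust(base[j])
        cum = np.cumsum(probs, axis=1)
        u = rng.random(at.size)
        # next state: first target whose cumulative probability exceeds u
        nxt = (u[:, None] < cum).argmax(axis=1)
        exited = u >= cum[:, -1]
        nxt_state = np.where(exited, n, si + 1 + nxt)
        state[at] = nxt_state
        moved = at[~exited]
        if moved.size:
            flags[moved, nxt_state[~exited]] = 1

    # women still sitting at the last intervention have given birth
    counts: dict[tuple[int, ...], int] = {}
    uniq, cnt = np.unique(flags, axis=0, return_counts=True)
    for row, c in zip(uniq, cnt):
        counts[tuple(int(x) for x in row)] = int(c)
    return PathCountTable(protocol, counts)


def recovery_experiment(
    config: SimulationConfig, replicates: int
) -> pd.DataFrame:
    """Bias and RMSE of the PP estimator over repeated simulated cohorts.

    One row per progression proportion: generative truth, mean estimate,
    bias, RMSE and how many replicates left the entry undefined (source state
    never reached).  Replicate seeds are spawned deterministically from the
    config seed.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(replicates)
    pairs = config.pps.pairs()
    estimates: dict[tuple[str, str], list[float]] = {p: [] for p in pairs}
    undefined = {p: 0 for p in pairs}

    for child in children:
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        rep = SimulationConfig(config.pps, config.n_women, seed, config.modifiers)
        table = simulate_cohort(rep)
        if table.N == 0:
            for p in pairs:
                undefined[p] += 1
            continue
        est = estimate_progression_proportions(table)
        for p in pairs:
            if p in est.undefined:
                undefined[p] += 1
            else:
                estimates[p].append(float(est.pp[p]))

    rows = []
    for p in pairs:
        truth = float(config.pps.pp.get(p, 0.0))
        vals = np.array(estimates[p], dtype=float)
        rows.append(
            {
                "pp": "->".join(p),
                "truth": truth,
                "n_defined": len(vals),
                "n_undefined": undefined[p],
                "mean_estimate": float(vals.mean()) if len(vals) else float("nan"),
                "bias": float(vals.mean() - truth) if len(vals) else float("nan"),
                "rmse": float(np.sqrt(np.mean((vals - truth) ** 2)))
                if len(vals)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
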