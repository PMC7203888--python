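"""Statistical comparison of two cohorts' pathway data.

Two operations: the chi-square test of homogeneity between the multinomial
path distributions of two cohorts (with sparse-cell pooling, since several of
the 2^n paths are typically rare), and the two-sample proportion test used to
compare individual type-specific ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .protocol import PathCountTable, ProtocolError

__all__ = [
    "PathComparisonResult",
    "ProportionTestResult",
    "compare_path_distributions",
    "compare_proportions",
]


@dataclass(frozen=True)
class PathComparisonResult:
    """Chi-square homogeneity test on the 2×k table of pooled path counts."""

    categories: tuple[str, ...]
    observed: tuple[tuple[int, ...], tuple[int, ...]]  # per cohort
    statistic: float
    df: int
    p_value: float
    method: str
    pooling_log: tuple[str, ...] = ()
    n_mc: int | None = None

    def as_dict(self) -> dict:
        return {
            "categories": list(self.categories),
            "observed": [list(r) for r in self.observed],
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "method": self.method,
            "pooling_log": list(self.pooling_log),
            "n_mc": self.n_mc,
        }


def _path_name(path: tuple[int, ...]) -> str:
    return "(" + ",".join(map(str, path)) + ")"


def _pool_sparse(
    names: list[str],
    counts1: np.ndarray,
    counts2: np.ndarray,
    min_expected: float,
) -> tuple[list[str], np.ndarray, np.ndarray, list[str]]:
    """Merge the sparsest category into "other" until all expected >= threshold.

    The category with the smallest total expected count (equivalently, the
    smallest combined observed count, since expected is proportional to the
    category total under homogeneity) is merged first; "other" itself keeps
    absorbing categories while any expected cell stays below the threshold.
    """
    names = list(names)
    c1 = counts1.astype(float).copy()
    c2 = counts2.astype(float).copy()
    log: list[str] = []

    def expected(c1, c2):
        col = c1 + c2
        grand = col.sum()
        return np.outer(
            np.array([c1.sum(), c2.sum()]) / grand, col
        ) * 1.0  # 2 x k matrix of expected counts

    while True:
        exp = expected(c1, c2)
        if exp.min() >= min_expected or len(names) <= 2:
            break
        totals = c1 + c2
        if "other" in names:
            # never pick "other" itself as the victim unless it is smallest
            order = np.argsort(totals, kind="stable")
        else:
            order = np.argsort(totals, kind="stable")
        victim = int(order[0])
        if names[victim] == "other" and len(names) > 1:
            victim = int(order[1])
        if "other" not in names:
            log.append(f"created 'other' from {names[victim]}")
            names[victim] = "other"
            continue
        other = names.index("other")
        log.append(f"pooled {names[victim]} into 'other'")
        c1[other] += c1[victim]
        c2[other] += c2[victim]
        c1 = np.delete(c1, victim)
        c2 = np.delete(c2, victim)
        del names[victim]
    return names, c1, c2, log


def compare_path_distributions(
    table1: PathCountTable,
    table2: PathCountTable,
    min_expected: float = 5.0,
    method: str = "chi2",
    n_mc: int = 10000,
    seed: int | None = None,
) -> PathComparisonResult:
    """Test homogeneity of two cohorts' path distributions.

    Categories (paths) whose expected count under homogeneity falls below
    ``min_expected`` are pooled into an ``other`` category, and the pooling is
    logged.  ``method="chi2"`` uses the asymptotic chi-square test of
    homogeneity; ``method="mc"`` calibrates the same statistic by Monte-Carlo
    resampling from the pooled distribution (for tables where the asymptotic
    caveats bite).
    """
    if table1.protocol.labels != table2.protocol.labels:
        raise ProtocolError("cohorts must share a protocol")
    table1.require_nonempty()
    table2.require_nonempty()

    paths = [tuple(p.flags) for p in table1.paths()]
    names = [_path_name(p) for p in paths]
    c1 = np.array([table1.count(p) for p in paths], dtype=float)
    c2 = np.array([table2.count(p) for p in paths], dtype=float)

    # drop paths observed in neither cohort (zero columns carry no information)
    keep = (c1 + c2) > 0
    names = [n for n, k in zip(names, keep) if k]
    c1, c2 = c1[keep], c2[keep]

    names, c1, c2, log = _pool_sparse(names, c1, c2, min_expected)
    if len(names) < 2:
        raise ValueError("fewer than 2 categories after pooling; test undefined")

    obs = np.vstack([c1, c2])
    res = sps.chi2_contingency(obs, correction=False)
    stat, df = float(res.statistic), int(res.dof)

    if method == "chi2":
        p = float(res.pvalue)
        used = "chi2_homogeneity"
        mc_used = None
    elif method == "mc":
        rng = np.random.default_rng(seed)
        pooled = (c1 + c2) / (c1.sum() + c2.sum())
        n1, n2 = int(c1.sum()), int(c2.sum())
        sims1 = rng.multinomial(n1, pooled, size=n_mc).astype(float)
        sims2 = rng.multinomial(n2, pooled, size=n_mc).astype(float)
        col = sims1 + sims2
        with np.errstate(divide="ignore", invalid="ignore"):
            e1 = col * (n1 / (n1 + n2))
            e2 = col * (n2 / (n1 + n2))
            stats_mc = np.nansum(
                np.where(e1 > 0, (sims1 - e1) ** 2 / e1, 0.0)
                + np.where(e2 > 0, (sims2 - e2) ** 2 / e2, 0.0),
                axis=1,
            )
        p = float((1 + np.sum(stats_mc >= stat - 1e-12)) / (1 + n_mc))
        used = "chi2_monte_carlo"
        mc_used = n_mc
    else:
        raise ValueError(f"unknown method {method!r}; use 'chi2' or 'mc'")

    return PathComparisonResult(
        categories=tuple(names),
        observed=(tuple(int(x) for x in c1), tuple(int(x) for x in c2)),
        statistic=stat,
        df=df,
        p_value=p,
        method=used,
        pooling_log=tuple(log),
        n_mc=mc_used,
    )


@dataclass(frozen=True)
class ProportionTestResult:
    statistic: float
    p_value: float
    note: str | None = None


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> ProportionTestResult:
    """Two-sided test of equal proportions k1/n1 vs k2/n2.

    Pearson chi-square on the 2×2 table, without Yates continuity correction
    by default (``correction=True`` enables it).  Degenerate margins (no
    successes or no failures anywhere) give statistic 0 and p = 1 with a note.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not (0 <= k <= n):
            raise ValueError(f"invalid counts: k={k}, n={n}")
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0:
        return ProportionTestResult(
            0.0, 1.0, note="degenerate margin: all successes or all failures"
        )
    tbl = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    res = sps.chi2_contingency(tbl, correction=correction)
    return ProportionTestResult(float(res.statistic), float(res.pvalue))
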