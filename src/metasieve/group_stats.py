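"""Group-level comparison of per-sample microbial fractions.

The Mann-Whitney U test compares the distributions of per-sample microbial
fractions (PPM) between two groups.  U counts pairs (x_i, y_j) with
x_i > y_j, plus half the ties (midranks).  The exact branch uses the exact
null distribution of U (tie-free) or full enumeration over group-label
assignments (with ties); the approximate branch uses the tie-corrected
normal approximation with continuity correction.  Two-sided p by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .abundance import CountMatrix, microbial_fraction

__all__ = ["MannWhitneyResult", "GroupComparison", "mann_whitney", "group_fraction_comparison"]

_EXACT_LIMIT = 400  # n1*n2 bound for the auto exact branch
_ENUM_LIMIT = 2_000_000  # combination cap for the tied exact enumeration


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str  # "exact" or "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def _exact_enumeration(x: np.ndarray, y: np.ndarray, alternative: str) -> MannWhitneyResult:
    # Enumerate every assignment of the pooled values into the two groups,
    # computing U from midranks; valid with or without ties.
    n1, n2 = len(x), len(y)
    n = n1 + n2
    if math.comb(n, n1) > _ENUM_LIMIT:
        raise ValueError(
            f"exact enumeration with ties infeasible for C({n},{n1}) splits; "
            "use mode='normal-approx'"
        )
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2
    u_obs = float(ranks[:n1].sum() - offset)
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)]
    )
    eps = 1e-9
    cdf = np.mean(us <= u_obs + eps)
    sf = np.mean(us >= u_obs - eps)
    if alternative == "two-sided":
        p = min(1.0, 2.0 * min(cdf, sf))
    elif alternative == "greater":
        p = sf
    else:
        p = cdf
    return MannWhitneyResult(u=u_obs, p=float(p), method="exact")


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> MannWhitneyResult:
    """Mann-Whitney U test of ``x`` vs ``y``.

    ``mode``: ``"exact"`` forces the exact null distribution (enumeration
    when ties are present), ``"normal-approx"`` forces the tie-corrected
    normal approximation with continuity correction, and ``"auto"``
    (default) uses exact when ``n1*n2 <= 400`` and the data are tie-free.
    """
    if mode not in ("auto", "exact", "normal-approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = (
            "exact" if (len(x) * len(y) <= _EXACT_LIMIT and not has_ties) else "normal-approx"
        )
    if mode == "exact":
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
            return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="exact")
        return _exact_enumeration(x, y, alternative)
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(u=float(res.statistic), p=float(res.pvalue), method="asymptotic")


@dataclass
class GroupComparison:
    """Two-group comparison of per-sample microbial fractions."""

    group_a: str
    group_b: str
    values_a: dict[str, float]
    values_b: dict[str, float]
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    u: float
    p: float
    method: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return mean, sem


def group_fraction_comparison(
    cm: CountMatrix,
    group_a: str = "MS",
    group_b: str = "control",
    mode: str = "auto",
    alternative: str = "two-sided",
) -> GroupComparison:
    """Compare per-sample microbial fractions (PPM) between two groups."""
    samples_a = cm.samples_in_group(group_a)
    samples_b = cm.samples_in_group(group_b)
    if not samples_a or not samples_b:
        raise ValueError(f"empty group among ({group_a!r}, {group_b!r})")
    va = {s: microbial_fraction(cm, s) for s in samples_a}
    vb = {s: microbial_fraction(cm, s) for s in samples_b}
    a = np.array(list(va.values()))
    b = np.array(list(vb.values()))
    mean_a, sem_a = _mean_sem(a)
    mean_b, sem_b = _mean_sem(b)
    mw = mann_whitney(a, b, mode=mode, alternative=alternative)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        values_a=va,
        values_b=vb,
        mean_a=mean_a,
        sem_a=sem_a,
        mean_b=mean_b,
        sem_b=sem_b,
        u=mw.u,
        p=mw.p,
        method=mw.method,
    )
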