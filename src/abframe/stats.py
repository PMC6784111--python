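"""Cross-variant statistics: Spearman correlation, ANOVA/Tukey, fold checks.

Spearman's rank correlation between thermal stability (Tm) and expression
titer uses an exact permutation p-value for small panels (n <= 10, the full
n! permutation null of the rank statistic) and the t-approximation
otherwise. The default alternative is one-sided positive, reflecting the
directional stability -> expression hypothesis; two-sided is available.

Group comparisons follow the screen-then-test convention: a
Kolmogorov-Smirnov normality check per group, one-way ANOVA, and Tukey's
HSD post-hoc adjustment (studentized range; Tukey-Kramer for unequal n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

EXACT_PERMUTATION_MAX_N = 10


@dataclass
class VariantSummary:
    name: str
    titer_replicates: Sequence[float]  # mg/L
    tm: float                          # degC
    kD: float                          # M

    def __post_init__(self):
        if len(self.titer_replicates) < 1:
            raise ValueError("need >= 1 titer replicate")
        if min(self.titer_replicates) <= 0 or self.tm <= 0 or self.kD <= 0:
            raise ValueError("all values must be positive")

    @property
    def mean_titer(self) -> float:
        return float(np.mean(self.titer_replicates))


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    p_method: str  # "exact-permutation" or "t-approximation"
    alternative: str

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho out of [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p out of [0, 1]")


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float,
                         alternative: str) -> float:
    """Exact permutation p for the rank correlation, over all n! orderings.

    Permuting one rank vector leaves its centered sum of squares unchanged,
    so only the cross-products vary; the statistic is evaluated in chunks.
    """
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    total = math.factorial(n)
    eps = 1e-12
    count = 0
    chunk_size = 200_000
    perm_iter = itertools.permutations(ryc)
    while True:
        chunk = list(itertools.islice(perm_iter, chunk_size))
        if not chunk:
            break
        rhos = np.asarray(chunk) @ rxc / denom
        if alternative == "greater":
            count += int(np.sum(rhos >= rho_obs - eps))
        elif alternative == "less":
            count += int(np.sum(rhos <= rho_obs + eps))
        else:
            count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - eps))
    return count / total


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "greater",
    method: str = "auto",
) -> CorrelationResult:
    """Spearman rank correlation with an exact small-sample p-value.

    `method` is "auto" (exact for n <= 10), "exact-permutation", or
    "t-approximation". Ties receive average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need >= 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "auto":
        method = ("exact-permutation" if n <= EXACT_PERMUTATION_MAX_N
                  else "t-approximation")
    if method == "exact-permutation":
        p = _exact_permutation_p(rx, ry, rho, alternative)
    elif method == "t-approximation":
        p = float(sps.spearmanr(x, y, alternative=alternative).pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, p_value=p, n=n, p_method=method,
                             alternative=alternative)


def spearman_tm_titer(
    summaries: Sequence[VariantSummary],
    alternative: str = "greater",
    method: str = "auto",
) -> CorrelationResult:
    """Correlation between variant Tm and mean expression titer."""
    tm = [s.tm for s in summaries]
    titer = [s.mean_titer for s in summaries]
    return spearman_correlation(tm, titer, alternative=alternative, method=method)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    normality_p: Dict[str, float]   # KS test per group
    tukey: pd.DataFrame             # pairwise adjusted comparisons


def anova_tukey(groups: Dict[str, Sequence[float]], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc, after a KS normality screen.

    Each group is standardized and tested against the standard normal
    (Kolmogorov-Smirnov); the screen is reported, not enforced.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")

    normality = {}
    for name, arr in arrays.items():
        sd = arr.std(ddof=1)
        z = (arr - arr.mean()) / sd if sd > 0 else arr - arr.mean()
        normality[name] = float(sps.kstest(z, "norm").pvalue)

    f_stat, p = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    hsd = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    return AnovaResult(f_statistic=float(f_stat), p_value=float(p),
                       normality_p=normality, tukey=tukey)


@dataclass
class FoldCheckResult:
    max_fold: float
    max_variant: str
    passed: bool
    folds: Dict[str, float]


def fold_check(
    values: Dict[str, float], reference: str, bound: float = 2.0
) -> FoldCheckResult:
    """Largest fold-difference of each value vs a reference; pass iff <= bound.

    The fold for a variant is max(v/ref, ref/v), so the check is invariant to
    a global rescaling of all values. The bound is inclusive.
    """
    if any(v <= 0 for v in values.values()):
        raise ValueError("all values must be positive")
    ref = values[reference]
    folds = {k: max(v / ref, ref / v) for k, v in values.items()}
    others = {k: f for k, f in folds.items() if k != reference} or folds
    max_variant = max(others, key=others.get)
    max_fold = others[max_variant]
    return FoldCheckResult(max_fold=float(max_fold), max_variant=max_variant,
                           passed=bool(max_fold <= bound), folds=folds)
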