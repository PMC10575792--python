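"""Statistical battery for correlative ROI and turnover data.

Linear-regression slope tests and two-tailed Pearson correlations for the
marker-vs-ion comparisons, Bonferroni correction across compared parameters
(reported both capped at 1 and uncapped — figure legends in this field
sometimes print the raw p*m product, e.g. P = 3.383), and Kruskal-Wallis
with Dunn's post-hoc pairwise z-tests for isotope-turnover group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["TestResult", "linreg_test", "pearson_test", "bonferroni",
           "apply_bonferroni", "kruskal_dunn", "dunn_pairwise"]


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    n: int
    estimate: float | None = None
    r_squared: float | None = None
    p_bonferroni_uncapped: float | None = None
    p_bonferroni_capped: float | None = None
    extra: dict = field(default_factory=dict)


def bonferroni(p_values, m: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni-adjusted p-values, (uncapped, capped).

    ``uncapped = p*m`` reproduces printed values above 1; ``capped``
    clamps at 1.  ``m`` defaults to the family size len(p_values).
    """
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    uncapped = p * m
    return uncapped, np.minimum(1.0, uncapped)


def apply_bonferroni(result: TestResult, m: int) -> TestResult:
    unc, cap = bonferroni([result.p_raw], m)
    result.p_bonferroni_uncapped = float(unc[0])
    result.p_bonferroni_capped = float(cap[0])
    return result


def _check_xy(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    return x, y


def linreg_test(x, y, m: int | None = None) -> TestResult:
    """OLS slope with two-sided t-test for slope = 0 (n-2 df).

    A constant-y input is treated as the degenerate no-relationship case
    (slope 0, R^2 = 0, p = 1) so batch pipelines keep running.
    """
    x, y = _check_xy(x, y)
    if np.ptp(y) == 0:
        res = TestResult(statistic=0.0, p_raw=1.0, n=x.size,
                         estimate=0.0, r_squared=0.0,
                         extra={"intercept": float(y[0]), "slope": 0.0})
    else:
        fit = sps.linregress(x, y)
        t = fit.slope / fit.stderr if fit.stderr > 0 else np.inf
        res = TestResult(
            statistic=float(t), p_raw=float(fit.pvalue), n=x.size,
            estimate=float(fit.slope), r_squared=float(fit.rvalue ** 2),
            extra={"intercept": float(fit.intercept),
                   "slope": float(fit.slope),
                   "stderr": float(fit.stderr)})
    return apply_bonferroni(res, m) if m else res


def pearson_test(x, y, m: int | None = None) -> TestResult:
    """Two-tailed Pearson correlation test."""
    x, y = _check_xy(x, y)
    if np.ptp(y) == 0:
        raise ValueError("y is constant")
    r, p = sps.pearsonr(x, y)
    res = TestResult(statistic=float(r), p_raw=float(p), n=x.size,
                     estimate=float(r), r_squared=float(r ** 2))
    return apply_bonferroni(res, m) if m else res


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def dunn_pairwise(groups: Sequence[np.ndarray],
                  labels: Sequence | None = None,
                  adjust: str | None = None) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on joint ranks, with tie correction.

    For groups i, j with mean ranks Rbar_i, Rbar_j in the pooled ranking of
    N observations:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
        T = sum(t^3 - t) / (12 (N - 1))  over tie groups.

    Two-sided p from the standard normal.  ``adjust='bonferroni'``
    multiplies by the number of pairs (capped at 1); default is unadjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [g.size for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    tie = _tie_term(pooled) / (12.0 * (N - 1)) if N > 1 else 0.0
    var0 = N * (N + 1) / 12.0 - tie
    rows = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((labels[i], labels[j], float(z), float(p)))
    table = pd.DataFrame(rows, columns=["group_1", "group_2", "z", "p"])
    if adjust == "bonferroni":
        table["p_adjusted"] = np.minimum(1.0, table["p"] * len(table))
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return table


def kruskal_dunn(groups: Sequence, labels: Sequence | None = None,
                 adjust: str | None = None) -> tuple[TestResult, pd.DataFrame]:
    """Tie-corrected Kruskal-Wallis H test plus Dunn pairwise table.

    All-identical pooled data (H undefined) is reported as H = 0, p = 1:
    indistinguishable groups.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    try:
        with np.errstate(invalid="ignore"):
            H, p = sps.kruskal(*groups)
        if np.isnan(H):
            raise ValueError
    except ValueError:
        # all pooled values identical: H is 0/0, report indistinguishable
        H, p = 0.0, 1.0
    n = int(sum(g.size for g in groups))
    result = TestResult(statistic=float(H), p_raw=float(p), n=n,
                        extra={"df": len(groups) - 1})
    return result, dunn_pairwise(groups, labels=labels, adjust=adjust)
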