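"""Statistical machinery for omega (Ka/Ks) analyses.

Covers maximum-likelihood distribution fitting with Q-Q goodness ranking,
the shared-vs-separate two-group likelihood-ratio test, subsampling
bootstrap tests on group means, Mann-Whitney U (exact by enumeration for
small tie-free samples), 2x2 chi-square, UPGMA clustering of compartments
by mean omega with nested Mann-Whitney comparisons, and correlation
analyses (Pearson/Spearman, optionally on log10-transformed x).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InvalidParameterError

# family name -> (scipy distribution, fixed fit kwargs, free parameter count,
#                 positive support)
FAMILIES: dict[str, tuple] = {
    "weibull": (stats.weibull_min, {"floc": 0.0}, 2, True),
    "gamma": (stats.gamma, {"floc": 0.0}, 2, True),
    "exponential": (stats.expon, {"floc": 0.0}, 1, True),
    "logistic": (stats.logistic, {}, 2, False),
    "normal": (stats.norm, {}, 2, False),
    "extreme_value": (stats.genextreme, {}, 3, False),
    "lognormal": (stats.lognorm, {"floc": 0.0}, 2, True),
    "cauchy": (stats.cauchy, {}, 2, False),
}


@dataclass
class FitResult:
    family: str
    params: tuple[float, ...]
    loglik: float
    k: int
    qq_r: float | None = None
    converged: bool = True


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    alternative: str = "two-sided"
    n: int | None = None
    note: str | None = None


def _check_family(family: str):
    if family not in FAMILIES:
        raise InvalidParameterError(f"unknown distribution family {family!r}")
    return FAMILIES[family]


def fit_distribution(data: Sequence[float], family: str) -> FitResult:
    """Maximum-likelihood fit of one distribution family.

    Positive-support families (Weibull, gamma, exponential, log-normal) are
    fit with location fixed at zero and require strictly positive data; the
    exponential rate is the closed-form 1/mean.  Non-convergence yields a
    flagged (``converged=False``) result instead of an exception.
    """
    dist, fixed, k, positive = _check_family(family)
    x = np.asarray(data, dtype=float)
    if x.size < 5:
        raise InvalidParameterError("need at least 5 observations")
    if positive and (x <= 0).any():
        raise InvalidParameterError(
            f"family {family!r} requires strictly positive data"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = dist.fit(x, **fixed)
            loglik = float(np.sum(dist.logpdf(x, *params)))
        converged = math.isfinite(loglik)
    except Exception:
        params, loglik, converged = (math.nan,) * (k + 1), -math.inf, False
    return FitResult(family, tuple(params), loglik, k, converged=converged)


def qq_pearson_r(data: Sequence[float], fit: FitResult) -> float:
    """Pearson correlation of theoretical quantiles at plotting positions
    (i - 0.5)/n against the sorted data."""
    dist = _check_family(fit.family)[0]
    x = np.sort(np.asarray(data, dtype=float))
    if np.ptp(x) == 0:
        raise InvalidParameterError("constant data: Q-Q correlation undefined")
    n = x.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    theoretical = dist.ppf(probs, *fit.params)
    finite = np.isfinite(theoretical)
    r, _ = stats.pearsonr(theoretical[finite], x[finite])
    return float(r)


def rank_distributions(
    data: Sequence[float], families: Iterable[str] | None = None
) -> pd.DataFrame:
    """Fit several families and rank them by Q-Q correlation.

    Positive-support families are skipped for data with nonpositive values.
    Ties in qq_r break by log-likelihood, so the top family is unique.
    """
    rows = []
    for family in families or FAMILIES:
        positive = FAMILIES[family][3]
        if positive and (np.asarray(data) <= 0).any():
            continue
        fit = fit_distribution(data, family)
        fit.qq_r = qq_pearson_r(data, fit) if fit.converged else math.nan
        rows.append((family, fit.qq_r, fit.k, fit.loglik, fit.params))
    df = pd.DataFrame(rows, columns=["family", "qq_r", "k", "loglik", "params"])
    return df.sort_values(
        ["qq_r", "loglik"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def two_group_lrt(
    x: Sequence[float], y: Sequence[float], family: str
) -> TestResult:
    """Likelihood-ratio test of separate vs shared distribution parameters.

    The null pools both groups into one fit of the family; the alternative
    fits each group separately (twice the parameters).  The statistic
    2*(lnL_x + lnL_y - lnL_pooled) is referred to a chi-square with k
    degrees of freedom, k the family's free-parameter count.
    """
    fx = fit_distribution(x, family)
    fy = fit_distribution(y, family)
    pooled = fit_distribution(np.concatenate([np.asarray(x), np.asarray(y)]), family)
    if not (fx.converged and fy.converged and pooled.converged):
        raise InvalidParameterError("a component fit failed to converge")
    statistic = 2.0 * (fx.loglik + fy.loglik - pooled.loglik)
    df = fx.k
    p = float(stats.chi2.sf(max(statistic, 0.0), df))
    return TestResult("two_group_lrt", statistic, p, df=df, n=len(x) + len(y))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test.

    Exact permutation enumeration when the combined sample is small
    (n_x + n_y <= 12) and tie-free; otherwise the normal approximation with
    tie correction (scipy).  ``alternative='less'`` tests whether x is
    stochastically smaller than y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx_, ny_ = x.size, y.size
    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    u_obs = float(np.sum(x[:, None] > y[None, :]))

    if nx_ + ny_ <= 12 and tie_free:
        ranks = stats.rankdata(combined)
        total = 0
        le = ge = 0
        rank_set = list(range(nx_ + ny_))
        for idx in combinations(rank_set, nx_):
            u = sum(ranks[list(idx)]) - nx_ * (nx_ + 1) / 2
            total += 1
            if u <= u_obs + 1e-12:
                le += 1
            if u >= u_obs - 1e-12:
                ge += 1
        if alternative == "less":
            p = le / total
        elif alternative == "greater":
            p = ge / total
        else:
            p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(
            "mann_whitney_exact", u_obs, p, alternative=alternative, n=nx_ + ny_
        )
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(
        "mann_whitney", float(res.statistic), float(res.pvalue),
        alternative=alternative, n=nx_ + ny_,
    )


def chisq_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise InvalidParameterError("need a nonnegative 2x2 table")
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if n == 0 or (rows == 0).any() or (cols == 0).any():
        raise InvalidParameterError("zero marginal in 2x2 table")
    a, b, c, d = t.ravel()
    statistic = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    p = float(stats.chi2.sf(statistic, 1))
    return TestResult("chisq_2x2", float(statistic), p, df=1, n=int(n))


def bootstrap_mean_test(
    pool: Sequence[float],
    n_sub: int,
    n_reps: int,
    observed_mean: float,
    tail: str = "less",
    seed: int = 0,
    replace: bool = False,
) -> TestResult:
    """Subsampling bootstrap on the mean.

    Draws ``n_reps`` samples of size ``n_sub`` from the pool (without
    replacement within a replicate by default) and reports
    p = (#{replicate means at or beyond the observed} + 1) / (n_reps + 1),
    so 'no case as extreme' over 1e6 replicates reports p < 1e-6.
    """
    pool = np.asarray(pool, dtype=float)
    if n_sub > pool.size and not replace:
        raise InvalidParameterError("n_sub exceeds the pool size")
    if tail not in ("less", "greater"):
        raise InvalidParameterError("tail must be 'less' or 'greater'")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_reps):
        sample = rng.choice(pool, size=n_sub, replace=replace)
        m = sample.mean()
        if (tail == "less" and m <= observed_mean) or (
            tail == "greater" and m >= observed_mean
        ):
            count += 1
    p = (count + 1) / (n_reps + 1)
    return TestResult(
        "bootstrap_mean", float(observed_mean), p, alternative=tail, n=n_reps
    )


def bootstrap_diff_test(
    pool: Sequence[float],
    n1: int,
    n2: int,
    n_reps: int,
    observed_diff: float,
    seed: int = 0,
) -> TestResult:
    """Two-sided bootstrap on the difference of two subsample means.

    Each replicate partitions a random draw of n1 + n2 pool values (without
    replacement) into two groups and records the difference of their means;
    p = (#{|replicate diff| >= |observed|} + 1) / (n_reps + 1).
    """
    pool = np.asarray(pool, dtype=float)
    if n1 + n2 > pool.size:
        raise InvalidParameterError("n1 + n2 exceeds the pool size")
    rng = np.random.default_rng(seed)
    count = 0
    threshold = abs(observed_diff)
    for _ in range(n_reps):
        draw = rng.choice(pool, size=n1 + n2, replace=False)
        diff = draw[:n1].mean() - draw[n1:].mean()
        if abs(diff) >= threshold:
            count += 1
    p = (count + 1) / (n_reps + 1)
    return TestResult("bootstrap_diff", float(observed_diff), p, n=n_reps)


@dataclass
class NestedComparison:
    left: tuple[str, ...]
    right: tuple[str, ...]
    test: TestResult
    significant: bool


def upgma_nested_tests(
    group_values: Mapping[str, Sequence[float]], alpha: float = 0.01
) -> tuple[str, list[NestedComparison]]:
    """UPGMA clustering of groups by mean, with nested Mann-Whitney tests.

    Groups (e.g. cellular compartments) are clustered by average linkage on
    the absolute differences of their mean values; labels are sorted so the
    dendrogram is deterministic.  Walking the merges from the leaves up,
    each internal node contributes one two-sided Mann-Whitney test between
    the pooled raw values of its two child clades (g - 1 comparisons for g
    groups instead of all pairwise ones).  Returns the tree as a newick
    string plus the ordered comparison list.
    """
    labels = sorted(group_values)
    if len(labels) < 2:
        raise InvalidParameterError("need at least two groups")
    means = np.array([np.mean(group_values[lab]) for lab in labels])
    dist = np.abs(means[:, None] - means[None, :])
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")

    clusters: dict[int, tuple[str, ...]] = {
        i: (lab,) for i, lab in enumerate(labels)
    }
    comparisons: list[NestedComparison] = []
    for row_idx, (i, j, _, _) in enumerate(linkage):
        left = clusters[int(i)]
        right = clusters[int(j)]
        pooled_left = np.concatenate([np.asarray(group_values[lab]) for lab in left])
        pooled_right = np.concatenate([np.asarray(group_values[lab]) for lab in right])
        test = mann_whitney(pooled_left, pooled_right, alternative="two-sided")
        comparisons.append(
            NestedComparison(left, right, test, test.p_value <= alpha)
        )
        clusters[len(labels) + row_idx] = left + right

    tree = hierarchy.to_tree(linkage)
    newick = _to_newick(tree, labels) + ";"
    return newick, comparisons


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left},{right})"


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    x_transform: str = "none",
) -> TestResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    ``x_transform='log10'`` log-transforms x (requires positive values);
    zero-variance input yields a flagged NaN result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need equal-length inputs of size >= 3")
    if x_transform == "log10":
        if (x <= 0).any():
            raise InvalidParameterError("log10 transform requires positive x")
        x = np.log10(x)
    elif x_transform != "none":
        raise InvalidParameterError(f"unknown transform {x_transform!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(
            f"correlation_{method}", math.nan, math.nan, n=x.size,
            note="zero variance: correlation undefined",
        )
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)  # average ranks for ties
    else:
        raise InvalidParameterError(f"unknown method {method!r}")
    return TestResult(f"correlation_{method}", float(r), float(p), n=x.size)


def max_expression(expr: pd.DataFrame) -> pd.Series:
    """Per-gene maximum expression across all experiment columns.

    Missing values are ignored; genes with no observed value are dropped
    with a warning.
    """
    if expr.shape[1] < 1:
        raise InvalidParameterError("expression table needs at least one column")
    maxima = expr.max(axis=1, skipna=True)
    all_missing = maxima.isna()
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} gene(s) with no observed expression",
            stacklevel=2,
        )
    return maxima[~all_missing]
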