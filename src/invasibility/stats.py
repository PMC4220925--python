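"""Univariate inferential toolbox for the invasibility analysis.

Contains the nonparametric battery the pipeline applies before any GLM
work: a rank-transformation analysis of covariance (ordinary ANCOVA run on
midranks, for comparing NNS density and richness across river types or
quality classes while controlling for a covariable), the Mann-Whitney U
test (reference vs disturbed contrasts), the two-proportion Z test
(frequency-of-occurrence contrasts), an iterative Spearman collinearity
screen, and first-axis PCA used to extract the dominant environmental
gradient as an ANCOVA covariable.

All tests are two-sided. Ties are handled with midranks throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    p_value: float
    method: str
    df: tuple[float, ...] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class PcaAxis:
    """First principal axis: unit-norm loadings, variance share, scores."""

    loadings: pd.Series
    variance_fraction: float
    scores: pd.Series


def rank_ancova(response: Sequence[float], group: Sequence,
                covariate: Sequence[float]) -> TestResult:
    """Rank-transformation ANCOVA for a group effect with one covariable.

    Response and covariate are replaced by midranks and an ordinary linear
    ANCOVA (group + covariate) is fitted to the ranked data; the returned F
    statistic tests the group factor on (g-1, n-g-1) degrees of freedom.
    This is the rank-transform approach of running the classical procedure
    on ranks, which is robust to the heavily skewed, zero-rich density data.

    A constant covariate carries no information and is dropped, in which
    case the test reduces exactly to the one-way ANOVA on ranks with
    (g-1, n-g) degrees of freedom.
    """
    y = np.asarray(response, dtype=float)
    g = np.asarray(group)
    x = np.asarray(covariate, dtype=float)
    if not (len(y) == len(g) == len(x)):
        raise ValueError("response, group and covariate must be equal length")
    levels, codes = np.unique(g, return_inverse=True)
    n, k = len(y), len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.min(np.bincount(codes)) < 2:
        raise ValueError("every group needs at least 2 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant response: rank ANCOVA F is undefined")

    ry = sps.rankdata(y)
    rx = sps.rankdata(x)
    use_cov = np.ptp(x) > 0
    # full design: intercept + (k-1) treatment dummies + ranked covariate
    dummies = np.zeros((n, k - 1))
    for j in range(1, k):
        dummies[codes == j, j - 1] = 1.0
    cov_cols = [rx] if use_cov else []
    full = np.column_stack([np.ones(n), dummies, *cov_cols])
    reduced = np.column_stack([np.ones(n), *cov_cols])

    rss_full = _rss(full, ry)
    rss_red = _rss(reduced, ry)
    df1, df2 = k - 1, n - k - 1 if use_cov else n - k
    if df2 <= 0:
        raise ValueError("not enough residual degrees of freedom")
    if rss_full <= 0:
        raise ValueError("saturated fit on ranks: F is undefined")
    f_stat = ((rss_red - rss_full) / df1) / (rss_full / df2)
    p = float(sps.f.sf(f_stat, df1, df2))
    return TestResult(float(f_stat), p, "rank ANCOVA", df=(df1, df2))


def _rss(design: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float],
                 method: str = "auto") -> TestResult:
    """Mann-Whitney U test with midrank ties and a tie-corrected Z.

    ``method`` is ``"asymptotic"`` (normal approximation with tie-corrected
    variance), ``"exact"`` (full enumeration of the permutation distribution
    of U, valid with ties) or ``"auto"`` (exact when n1+n2 <= 12). The U
    reported is U of ``sample_a``; U_a + U_b = n1*n2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if method == "auto":
        method = "exact" if n1 + n2 <= 12 else "asymptotic"

    mu = n1 * n2 / 2
    if method == "exact":
        p = _mann_whitney_exact_p(pooled, n1, u_a)
        z = np.nan
    elif method == "asymptotic":
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1)))
        var = n1 * n2 / 12 * ((n + 1) - tie_term)
        if var <= 0:  # every observation tied: U is exactly its null mean
            z, p = 0.0, 1.0
        else:
            z = (u_a - mu) / np.sqrt(var)
            p = float(2 * sps.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(u_a, p, f"Mann-Whitney U ({method})",
                      extra={"z": float(z), "u_b": n1 * n2 - u_a})


def _mann_whitney_exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of the pooled values.

    The permutation distribution of U is symmetric about n1*n2/2 (swapping
    group labels maps U to n1*n2-U), so the two-sided p is the probability
    of a deviation from the centre at least as large as observed.
    """
    n = len(pooled)
    n2 = n - n1
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2
    d_obs = abs(u_obs - mu) - 1e-12  # guard float fuzz on midranks
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= d_obs:
            hits += 1
    return hits / total


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TestResult:
    """Two-sided Z test comparing two binomial proportions (pooled variance)."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n and n > 0 for both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is 0 or 1: Z is undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return TestResult(float(z), float(2 * sps.norm.sf(abs(z))),
                      "two-proportion Z", extra={"p1": p1, "p2": p2})


def spearman_screen(variables: pd.DataFrame, threshold: float = 0.75,
                    priorities: Sequence[str] | None = None) -> list[str]:
    """Iteratively drop collinear variables by Spearman rank correlation.

    While any retained pair has |rho| > ``threshold`` with p < 0.05, the
    lowest-priority variable involved in an offending pair is removed.
    ``priorities`` lists variables from most to least important (a stand-in
    for the expert judgement of each variable's ecological relevance);
    variables not listed rank below listed ones, in column order. The
    retained set, in original column order, has no offending pair left.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if len(variables) < 3:
        raise ValueError("need at least 3 observations to screen")
    cols = list(variables.columns)
    order = list(priorities or [])
    unknown = set(order) - set(cols)
    if unknown:
        raise ValueError(f"unknown priority variables: {sorted(unknown)}")
    rank = {c: (order.index(c) if c in order else len(order) + cols.index(c))
            for c in cols}

    retained = list(cols)
    while True:
        offending: set[str] = set()
        for v1, v2 in itertools.combinations(retained, 2):
            rho, p = sps.spearmanr(variables[v1], variables[v2])
            if abs(rho) > threshold and p < 0.05:
                offending.add(v1)
                offending.add(v2)
        if not offending:
            return retained
        drop = max(offending, key=lambda c: rank[c])
        retained.remove(drop)


def pca_first_axis(variables: pd.DataFrame) -> PcaAxis:
    """First principal component of the standardised variables.

    Variables are z-scored (correlation-scale PCA, appropriate for
    environmental variables with incommensurate units); the sign is fixed so
    the loading of largest magnitude is positive. The per-site scores serve
    as the synthetic environmental-gradient covariable.
    """
    if variables.shape[1] < 2 or variables.shape[0] < 3:
        raise ValueError("need at least 2 variables and 3 sites")
    if variables.isna().any().any():
        raise ValueError("missing values are not allowed")
    sd = variables.std(ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance variables: {dead}")
    z = (variables - variables.mean()) / sd
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())[:, 0]
    loadings = pca.components_[0]
    sign = np.sign(loadings[np.argmax(np.abs(loadings))]) or 1.0
    return PcaAxis(
        loadings=pd.Series(sign * loadings, index=variables.columns),
        variance_fraction=float(pca.explained_variance_ratio_[0]),
        scores=pd.Series(sign * scores, index=variables.index),
    )


def tidy_results(results: dict[str, TestResult]) -> pd.DataFrame:
    """Stack named test results into a tidy frame (test, statistic, df, p)."""
    rows = []
    for name, r in results.items():
        rows.append({
            "test": name, "method": r.method, "statistic": r.statistic,
            "df": "" if r.df is None else ",".join(str(d) for d in r.df),
            "p_value": r.p_value,
        })
    return pd.DataFrame(rows)
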