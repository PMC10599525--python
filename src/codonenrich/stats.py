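"""Vector-comparison statistics.

Correlations, PCA orthogonal regression, oriented within-block pairwise
synonymous differences, exact binomial sign tests, multivariate OLS and
Cronbach's alpha with the Feldt confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .enrichment import LogOddsVector
from .genetic_code import GeneticCodePartition


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int


@dataclass
class PairwiseDiffSet:
    """Oriented within-block synonymous differences of two vectors.

    Each pair is oriented so the x-vector difference dx is non-negative; the
    orientation carries over to dy.
    """

    pairs: list[tuple[str, str, float, float]]

    @property
    def dx(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs])

    @property
    def dy(self) -> np.ndarray:
        return np.array([p[3] for p in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AlphaResult:
    alpha: float
    ci_low: float
    ci_high: float
    k: int
    n: int


@dataclass
class FitResult:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    n: int


class DegenerateInputError(ValueError):
    """Input with no usable variance / spread."""


def _clean_pairs(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def correlate_vectors(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Undefined (NaN) entries are pairwise-dropped.
    """
    xv, yv = _clean_pairs(x, y)
    if len(xv) < 3:
        raise ValueError("need at least 3 paired finite values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateInputError("zero variance in one of the vectors")
    if method == "pearson":
        r, p = sps.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = sps.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method, float(r), float(p), len(xv))


def orthogonal_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Total-least-squares line via the first principal axis.

    The line passes through the centroid along the leading eigenvector of the
    2x2 covariance of the centered, unscaled data.  An isotropic cloud (tied
    eigenvalues) is an error rather than a silent choice.
    """
    xv, yv = _clean_pairs(x, y)
    if len(xv) < 2:
        raise ValueError("need at least 2 points")
    data = np.column_stack([xv, yv])
    centered = data - data.mean(axis=0)
    cov = centered.T @ centered / (len(xv) - 1)
    evals, evecs = np.linalg.eigh(cov)
    if math.isclose(evals[0], evals[1], rel_tol=1e-12, abs_tol=1e-300):
        raise DegenerateInputError("isotropic point cloud: principal axis is tied")
    v = evecs[:, int(np.argmax(evals))]
    if v[0] == 0:
        raise DegenerateInputError("principal axis is vertical; slope undefined")
    slope = v[1] / v[0]
    intercept = yv.mean() - slope * xv.mean()
    return float(slope), float(intercept)


def pairwise_synonym_diffs(
    x_vec: LogOddsVector, y_vec: LogOddsVector, code: GeneticCodePartition
) -> PairwiseDiffSet:
    """All intra-block codon-pair differences, oriented by the x vector.

    For the standard partition this yields exactly 87 pairs
    (9*1 + 1*3 + 5*6 + 3*15).  Pairs with an undefined member are dropped.
    dx ties are oriented by alphabetical codon order.
    """
    if set(x_vec.codons) != set(y_vec.codons):
        raise ValueError("vectors cover different codon sets")
    pairs: list[tuple[str, str, float, float]] = []
    for block in code.blocks:
        scored = sorted(c for c in block if c in x_vec.entries)
        for i in range(len(scored)):
            for j in range(i + 1, len(scored)):
                a, b = scored[i], scored[j]
                xa, xb = x_vec[a].log_odds, x_vec[b].log_odds
                ya, yb = y_vec[a].log_odds, y_vec[b].log_odds
                if not all(map(math.isfinite, (xa, xb, ya, yb))):
                    continue
                if xa >= xb:  # ties keep alphabetical order (a before b)
                    pairs.append((a, b, xa - xb, ya - yb))
                else:
                    pairs.append((b, a, xb - xa, yb - ya))
    return PairwiseDiffSet(pairs)


def sign_binomial_test(
    vector: LogOddsVector,
    subset: Callable[[str], bool],
    direction: str = "positive",
) -> tuple[int, int, float, int]:
    """Exact two-sided sign test on the log-odds signs of a codon subset.

    Returns (k, n, p, n_zero): k entries strictly matching ``direction`` out
    of n subset codons, with zero-valued entries counted as non-matching and
    reported separately.  p = min(1, 2 * smaller tail) under Binomial(n, 1/2).
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    values = [
        vector[c].log_odds
        for c in vector.codons
        if subset(c) and math.isfinite(vector[c].log_odds)
    ]
    n = len(values)
    if n == 0:
        raise ValueError("empty codon subset")
    if direction == "positive":
        k = sum(1 for v in values if v > 0)
    else:
        k = sum(1 for v in values if v < 0)
    n_zero = sum(1 for v in values if v == 0)
    return k, n, exact_binomial_two_sided(k, n), n_zero


def exact_binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p by pmf summation: min(1, 2 * smaller tail)."""
    lower = float(sps.binom.cdf(k, n, p0))
    upper = float(sps.binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))


def third_base_subset(bases: str) -> Callable[[str], bool]:
    """Predicate selecting codons by third base, e.g. third_base_subset('AT')."""
    wanted = set(bases.upper())
    return lambda codon: codon[2] in wanted


def multivariate_fit(
    response: Sequence[float],
    predictors: Mapping[str, Sequence[float]],
    include_quadratic: Sequence[str] = (),
) -> FitResult:
    """OLS with intercept; optional squared terms for named predictors."""
    y = np.asarray(response, dtype=float)
    names = list(predictors)
    cols = {name: np.asarray(predictors[name], dtype=float) for name in names}
    for name in include_quadratic:
        cols[f"{name}^2"] = cols[name] ** 2
    X = np.column_stack(list(cols.values()))
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[mask], X[mask]
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the requested model")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DegenerateInputError(
            f"rank-deficient design; columns: {['const', *cols]}"
        )
    fit = sm.OLS(y, Xc).fit()
    col_names = ["const", *cols]
    return FitResult(
        coefficients=dict(zip(col_names, fit.params)),
        standard_errors=dict(zip(col_names, fit.bse)),
        p_values=dict(zip(col_names, fit.pvalues)),
        adjusted_r2=float(fit.rsquared_adj),
        n=int(fit.nobs),
    )


def cronbach_alpha(matrix: np.ndarray, conf: float = 0.95) -> AlphaResult:
    """Cronbach's alpha over a subjects x items matrix, Feldt F-interval CI.

    alpha = k/(k-1) * (1 - sum of item sample variances / variance of totals).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 items")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite values")
    n, k = m.shape
    item_vars = m.var(axis=0, ddof=1)
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateInputError("zero variance of subject totals")
    alpha = k / (k - 1) * (1 - item_vars.sum() / total_var)
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    lo = 1 - (1 - alpha) * sps.f.ppf(1 - (1 - conf) / 2, df1, df2)
    hi = 1 - (1 - alpha) * sps.f.ppf((1 - conf) / 2, df1, df2)
    return AlphaResult(float(alpha), float(lo), float(hi), k, n)
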