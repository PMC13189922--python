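"""Statistical primitives shared by the methylome and transcriptome layers.

The differential-testing machinery follows the classical feature-wise
weighted-least-squares + empirical-Bayes variance-moderation scheme: each
feature g gets its own linear model against a common design matrix, the
residual variances s_g^2 are shrunk towards a pooled prior estimated by
moment-matching the distribution of log s_g^2 (a scaled F under the
hierarchical model), and the moderated t-statistic

    t_g = beta_g / (u_g * s_tilde_g),   s_tilde_g^2 = (d0*s0^2 + d_g*s_g^2) / (d0 + d_g)

is referred to a t distribution on d0 + d_g degrees of freedom.  Exact
enrichment (hypergeometric upper tail) and rank-sum tests are implemented
from first principles; scipy serves only as an independent cross-check in
the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "LmFit",
    "ModeratedResult",
    "FeatureCalls",
    "fit_feature_lm",
    "ebayes_moderate",
    "bh_adjust",
    "fisher_exact",
    "ranksum_exact",
    "quantile_normalize",
    "make_diff_table",
    "call_features",
    "DIFF_TABLE_COLUMNS",
]

#: Canonical column order of a differential table; downstream stages and the
#: TSV writers rely on these exact names.
DIFF_TABLE_COLUMNS = ["feature_id", "logFC", "t", "p_value", "q_value", "mean_level"]


@dataclass
class LmFit:
    """Feature-wise (weighted) least-squares fit.

    Attributes
    ----------
    coefficients : (G, k) array of estimated coefficients.
    stdev_unscaled : (G, k) array, u_g = sqrt(diag((X' W X)^-1)).
    sigma : (G,) residual standard deviations s_g.
    df_residual : residual degrees of freedom d_g = n - k (same for all g).
    amean : (G,) per-feature mean of the modeled values.
    feature_ids : optional feature labels carried through to results.
    """

    coefficients: np.ndarray
    stdev_unscaled: np.ndarray
    sigma: np.ndarray
    df_residual: int
    amean: np.ndarray
    feature_ids: np.ndarray | None = None
    design_colnames: list[str] | None = None


@dataclass
class ModeratedResult:
    """Empirical-Bayes moderated test on one coefficient."""

    prior_df: float
    prior_var: float
    coef: np.ndarray
    s_post: np.ndarray
    t: np.ndarray
    p_value: np.ndarray
    df_total: float
    amean: np.ndarray
    feature_ids: np.ndarray | None = None


@dataclass(frozen=True)
class FeatureCalls:
    """Thresholded up/down feature sets with the thresholds that produced them."""

    up: frozenset
    down: frozenset
    p_max: float
    min_abs_logfc: float

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)

    def __post_init__(self):
        overlap = self.up & self.down
        if overlap:
            raise StatsError(f"up/down call sets overlap: {sorted(overlap)[:5]}")


def _as_matrix(Y):
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), np.asarray(Y.index)
    return np.asarray(Y, dtype=float), None


def fit_feature_lm(Y, design, weights=None) -> LmFit:
    """Fit one linear model per feature (row of ``Y``) against ``design``.

    Parameters
    ----------
    Y : (G, n) array or DataFrame, features x samples.
    design : (n, k) full-column-rank design matrix (DataFrame or array).
    weights : optional (G, n) strictly positive observation weights.

    Returns
    -------
    LmFit with per-feature coefficients, unscaled coefficient standard
    deviations, residual sd and residual df n - k.
    """
    Ym, feature_ids = _as_matrix(Y)
    colnames = list(design.columns) if isinstance(design, pd.DataFrame) else None
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise StatsError("design must be 2-dimensional (samples x coefficients)")
    n, k = X.shape
    if Ym.shape[1] != n:
        raise StatsError(f"Y has {Ym.shape[1]} samples but design has {n} rows")
    if np.linalg.matrix_rank(X) < k:
        raise StatsError("design matrix is rank-deficient")
    if n <= k:
        raise StatsError(f"need more samples ({n}) than coefficients ({k})")

    G = Ym.shape[0]
    if weights is None:
        W = np.ones((G, n))
    else:
        W = np.asarray(weights, dtype=float)
        if W.shape != Ym.shape:
            raise StatsError("weights must have the same shape as Y")
        if not np.all(W > 0):
            raise StatsError("weights must be strictly positive")
        # Per-feature mean-1 normalization: the fit is invariant to weight
        # scale and residual variances stay comparable across features.
        W = W / W.mean(axis=1, keepdims=True)

    # Batched weighted normal equations: XtWX[g] = X' diag(w_g) X.
    XtWX = np.einsum("nk,gn,nl->gkl", X, W, X)
    XtWy = np.einsum("nk,gn,gn->gk", X, W, Ym)
    coef = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    cov_unscaled = np.linalg.inv(XtWX)
    stdev_unscaled = np.sqrt(np.diagonal(cov_unscaled, axis1=1, axis2=2))

    resid = Ym - coef @ X.T
    rss = np.einsum("gn,gn->g", W, resid**2)
    df_residual = n - k
    sigma = np.sqrt(np.maximum(rss, 0.0) / df_residual)

    return LmFit(
        coefficients=coef,
        stdev_unscaled=stdev_unscaled,
        sigma=sigma,
        df_residual=df_residual,
        amean=Ym.mean(axis=1),
        feature_ids=feature_ids,
        design_colnames=colnames,
    )


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma(x) = y; piecewise starts cover the tails.
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def _estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the empirical distribution of log s^2."""
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) if e.size > 1 else 0.0
    evar -= float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return d0, s0_sq


def ebayes_moderate(fit: LmFit, contrast: int, prior_df: float | None = None) -> ModeratedResult:
    """Moderated t-test on one design coefficient.

    The prior (d0, s0^2) is estimated by moment matching on log s_g^2 unless
    ``prior_df`` forces a value (0 reproduces the ordinary t-test, ``inf``
    fully pools the variances).
    """
    s2 = fit.sigma**2
    d = float(fit.df_residual)
    positive = s2 > 1e-20  # numerically-exact fits count as zero variance
    if not positive.any():
        raise StatsError(
            "all residual variances are zero; moderation is degenerate "
            "(add noise to the data or skip moderation)"
        )

    if prior_df is None:
        d0, s0_sq = _estimate_prior(s2[positive], d)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.mean(s2[positive])) if d0 > 0 else 0.0

    if math.isinf(d0):
        s_post = np.full_like(s2, math.sqrt(s0_sq))
        df_total = math.inf
    elif d0 == 0:
        s_post = np.sqrt(s2)
        df_total = d
    else:
        s_post = np.sqrt((d0 * s0_sq + d * s2) / (d0 + d))
        df_total = d0 + d

    coef = fit.coefficients[:, contrast]
    u = fit.stdev_unscaled[:, contrast]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (u * s_post)
    bad = ~np.isfinite(t)
    if bad.any():  # zero posterior sd: infinite evidence unless the coef is 0 too
        t = t.copy()
        t[bad] = np.sign(coef[bad]) * np.inf
        t[bad & (coef == 0)] = 0.0
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    return ModeratedResult(
        prior_df=d0,
        prior_var=s0_sq,
        coef=coef,
        s_post=s_post,
        t=t,
        p_value=p,
        df_total=df_total,
        amean=fit.amean,
        feature_ids=fit.feature_ids,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_exact(k: int, K: int, n: int, N: int) -> tuple[float, float]:
    """One-sided (enrichment) exact hypergeometric test.

    ``k`` query genes out of ``n`` fall inside a set of size ``K`` drawn from a
    universe of ``N``.  Returns the sample odds ratio and the exact upper-tail
    p-value P(X >= k), summed with rational arithmetic.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or N < K + n - k:
        raise StatsError(f"infeasible 2x2 table: k={k}, K={K}, n={n}, N={N}")
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    p = float(min(total, Fraction(1)))

    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, p


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def ranksum_exact(x, y) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses full enumeration of rank assignments when n_x + n_y <= 12 and the
    pooled data carry no ties; otherwise a tie-corrected normal approximation
    with continuity correction.  Returns (U, p, method) where method is
    ``"exact"`` or ``"normal"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    nx, ny = x.size, y.size
    u_obs = _mann_whitney_u(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if nx + ny <= 12 and not has_ties:
        ranks = np.arange(1, nx + ny + 1)
        mu = nx * ny / 2.0
        extreme = 0
        total = 0
        for combo in itertools.combinations(ranks, nx):
            u = sum(combo) - nx * (nx + 1) / 2.0
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                extreme += 1
        return u_obs, extreme / total, "exact"

    # Normal approximation with tie correction and continuity correction.
    n = nx + ny
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0, "normal"
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
    return u_obs, p, "normal"


def quantile_normalize(M):
    """Force every sample (column) onto the cross-column rank-wise mean
    distribution; ties within a column receive the mean of the quantiles they
    span.  Accepts and returns a DataFrame or ndarray."""
    is_df = isinstance(M, pd.DataFrame)
    A = M.to_numpy(dtype=float) if is_df else np.asarray(M, dtype=float)
    if np.isnan(A).any():
        raise StatsError("quantile normalization requires complete data")
    n_feat, n_samp = A.shape
    if n_samp < 2:
        warnings.warn("single sample: quantile normalization is the identity")
        out = A.copy()
    else:
        means = np.sort(A, axis=0).mean(axis=1)
        out = np.empty_like(A)
        grid = np.arange(1, n_feat + 1, dtype=float)
        for j in range(n_samp):
            ranks = sps.rankdata(A[:, j], method="average")
            out[:, j] = np.interp(ranks, grid, means)
    if is_df:
        return pd.DataFrame(out, index=M.index, columns=M.columns)
    return out


def make_diff_table(result: ModeratedResult, feature_ids=None) -> pd.DataFrame:
    """Assemble the canonical differential table from a moderated result."""
    ids = feature_ids if feature_ids is not None else result.feature_ids
    if ids is None:
        ids = np.arange(result.coef.size).astype(str)
    table = pd.DataFrame(
        {
            "feature_id": np.asarray(ids, dtype=object),
            "logFC": result.coef,
            "t": result.t,
            "p_value": result.p_value,
            "q_value": bh_adjust(result.p_value),
            "mean_level": result.amean,
        }
    )
    if table["feature_id"].duplicated().any():
        raise StatsError("duplicate feature identifiers in differential table")
    return table


def call_features(table: pd.DataFrame, p_max: float, min_fold: float) -> FeatureCalls:
    """Threshold a differential table into up/down calls.

    Convention mirrors the printed cutoffs: raw p strictly below ``p_max`` and
    |logFC| at or above log2(``min_fold``) on the modeled scale.
    """
    if min_fold < 1:
        raise StatsError("min_fold must be >= 1")
    lfc_min = math.log2(min_fold)
    sig = table["p_value"] < p_max
    up = frozenset(table.loc[sig & (table["logFC"] >= lfc_min), "feature_id"])
    down = frozenset(table.loc[sig & (table["logFC"] <= -lfc_min), "feature_id"])
    if lfc_min == 0:  # logFC exactly 0 would satisfy both directions
        down = down - up
    return FeatureCalls(up=up, down=down, p_max=p_max, min_abs_logfc=lfc_min)
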