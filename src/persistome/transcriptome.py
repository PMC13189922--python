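"""RNA-seq count analysis stage.

Low-count filtering on CPM, trimmed-mean-of-M-values (TMM) compositional
normalization, moderated log2-CPM, mean-variance precision weights in the
voom style (one global lowess trend, single pass), the paired factorial
differential-expression contrast, and PCA on the top-variance genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import stats
from .errors import DesignError, FilterError, StatsError
from .methylome import treatment_design

__all__ = [
    "NormFactors",
    "PCAResult",
    "filter_low_expression",
    "tmm_normalize",
    "log_cpm",
    "mean_variance_weights",
    "de_pipeline",
    "pca_top_features",
]


@dataclass
class NormFactors:
    """Per-sample library sizes and TMM factors (geometric mean 1)."""

    sample_ids: list
    lib_size: np.ndarray
    factor: np.ndarray

    @property
    def effective(self) -> np.ndarray:
        return self.lib_size * self.factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "lib_size": self.lib_size, "tmm_factor": self.factor}
        )


def filter_low_expression(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Keep genes with CPM > ``min_cpm`` in at least ``min_samples`` samples.

    Default ``min_samples`` is the smallest (arm, timepoint) group size among
    the sheet rows matching the count columns; row order is preserved.
    """
    sub = sheet[sheet["sample_id"].isin(counts.columns)]
    if min_samples is None:
        if len(sub) == 0:
            raise DesignError("no sheet rows match the count matrix columns")
        min_samples = int(sub.groupby(["arm", "timepoint"]).size().min())
    if min_samples > counts.shape[1]:
        raise FilterError("min_samples exceeds the number of samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise FilterError("every sample must have positive total counts")
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    out = counts.loc[keep]
    if out.shape[0] == 0:
        raise FilterError("low-expression filter removed every gene")
    return out


def _quantile_reference(counts: np.ndarray, lib: np.ndarray) -> int:
    # Reference sample: upper-quartile CPM closest to the mean upper quartile.
    f75 = np.array([np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair(y_k, y_r, N_k, N_r, logratio_trim=0.3, sum_trim=0.05) -> float:
    both = (y_k > 0) & (y_r > 0)
    if not both.any():
        raise StatsError("sample shares no positive genes with the TMM reference")
    yk, yr = y_k[both], y_r[both]
    M = np.log2((yk / N_k) / (yr / N_r))
    A = 0.5 * np.log2((yk / N_k) * (yr / N_r))
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    # Asymptotic (delta-method) variance of each M; precision weights are 1/v.
    v = (N_k - yk) / (N_k * yk) + (N_r - yr) / (N_r * yr)
    n = M.size
    loL = math.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = math.floor(n * sum_trim) + 1
    hiS = n + 1 - loS
    rM = pd.Series(M).rank().to_numpy()
    rA = pd.Series(A).rank().to_numpy()
    keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
    if not keep.any() or not np.all(v[keep] > 0):
        return 1.0
    f = float(np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    if not np.isfinite(f):
        return 1.0
    return 2.0**f


def tmm_normalize(counts: pd.DataFrame, ref_sample: str | None = None) -> NormFactors:
    """Trimmed mean of M-values normalization factors.

    Per sample vs the reference, gene-wise log-ratios M and abundances A are
    computed over genes positive in both; 30% of M extremes and 5% of A
    extremes are trimmed and the factor is 2^(precision-weighted mean M)
    with asymptotic binomial variance weights.  Factors are rescaled to
    geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise DesignError("TMM normalization needs at least 2 samples")
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    if np.any(lib <= 0):
        raise FilterError("every sample must have positive total counts")
    if ref_sample is None:
        ref = _quantile_reference(Y, lib)
    else:
        ref = list(counts.columns).index(ref_sample)
    factors = np.array(
        [
            1.0 if j == ref else _tmm_pair(Y[:, j], Y[:, ref], lib[j], lib[ref])
            for j in range(Y.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(sample_ids=list(counts.columns), lib_size=lib, factor=factors)


def log_cpm(counts: pd.DataFrame, factors: NormFactors, prior_count: float = 0.5) -> pd.DataFrame:
    """Moderated log2 counts per million on effective library sizes.

    Defined as log2(CPM + prior_count) with CPM = y / (N * f) * 1e6: the
    moderation prior lives on the CPM scale, so the transform is finite at
    zero counts and exactly invariant to globally rescaling counts and
    libraries together.
    """
    if prior_count <= 0:
        raise StatsError("prior_count must be > 0")
    L = factors.effective
    Y = counts.to_numpy(dtype=float)
    out = np.log2(Y / L[None, :] * 1e6 + prior_count)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def mean_variance_weights(
    counts: pd.DataFrame,
    factors: NormFactors,
    design,
    span: float = 0.5,
    prior_count: float = 0.5,
) -> np.ndarray:
    """voom-style precision weights from a single global mean-variance trend.

    An unweighted fit on log2-CPM supplies per-gene residual sd; lowess of
    sqrt(sd) against mean log2-count gives the trend, which is evaluated at
    each observation's fitted log2-count; weights are the inverse predicted
    variances.  Falls back to unit weights (with a warning) below 50 genes.
    """
    if counts.shape[0] < 50:
        warnings.warn("fewer than 50 genes: mean-variance trend unreliable, using unit weights")
        return np.ones(counts.shape)
    logcpm = log_cpm(counts, factors, prior_count)
    fit = stats.fit_feature_lm(logcpm, design)
    L = factors.effective
    sx = logcpm.to_numpy().mean(axis=1) + float(np.mean(np.log2(L + 1.0))) - math.log2(1e6)
    sy = np.sqrt(fit.sigma)
    trend = lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)

    X = np.asarray(design, dtype=float)
    fitted = fit.coefficients @ X.T  # fitted log2-CPM per observation
    fitted_logcount = fitted + np.log2(L + 1.0)[None, :] - math.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)
    return 1.0 / pred_sqrt_sd**4


def de_pipeline(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    arm: str,
    timepoint: str,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    prior_count: float = 0.5,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Full differential-expression contrast for one arm at one timepoint.

    filter -> TMM -> log2-CPM -> precision weights -> moderated linear model
    on the treatment coefficient; logFC is on the log2 scale.
    """
    sub, design = treatment_design(sheet, arm, timepoint)
    sample_ids = sub["sample_id"].tolist()
    missing = [s for s in sample_ids if s not in counts.columns]
    if missing:
        raise DesignError(f"count matrix lacks samples: {missing}")
    counts_sub = counts[sample_ids]
    kept = filter_low_expression(counts_sub, sub, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_normalize(kept)
    logcpm = log_cpm(kept, factors, prior_count)
    weights = (
        mean_variance_weights(kept, factors, design, prior_count=prior_count)
        if use_weights
        else None
    )
    fit = stats.fit_feature_lm(logcpm, design, weights=weights)
    result = stats.ebayes_moderate(fit, contrast=design.shape[1] - 1)
    return stats.make_diff_table(result, feature_ids=logcpm.index.to_numpy())


@dataclass
class PCAResult:
    """Sample scores, per-component variance fractions and the genes used."""

    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    features: list


def pca_top_features(logcpm: pd.DataFrame, n_top: int = 10000) -> PCAResult:
    """PCA of samples on the ``n_top`` most variable features.

    Features are ranked by descending variance (ties broken by feature id);
    each selected feature is centered across samples and the centered matrix
    is decomposed by SVD.  Scores are the sample projections.
    """
    if n_top < 2:
        raise DesignError("n_top must be >= 2")
    if logcpm.shape[1] < 3:
        raise DesignError("PCA needs at least 3 samples")
    if n_top > logcpm.shape[0]:
        warnings.warn(f"n_top={n_top} exceeds {logcpm.shape[0]} features; using all")
        n_top = logcpm.shape[0]
    variances = logcpm.var(axis=1, ddof=1)
    order = sorted(logcpm.index, key=lambda f: (-variances[f], str(f)))
    chosen = order[:n_top]
    X = logcpm.loc[chosen].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Vt.T * S[None, :]
    total = float(np.sum(S**2))
    frac = S**2 / total if total > 0 else np.zeros_like(S)
    n_comp = scores.shape[1]
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=logcpm.columns,
            columns=[f"PC{i + 1}" for i in range(n_comp)],
        ),
        variance_fraction=frac,
        features=list(chosen),
    )
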