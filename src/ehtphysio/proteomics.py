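"""Label-free proteomics preprocessing and differential abundance.

The chain mirrors a standard precursor-peak-area workflow:

1. :func:`normalize_abundance` — per-sample total-peak-area normalization,
   scaled so the grand mean of observed intensities is 100;
2. :func:`filter_missing` — drop proteins with > 30 % missing values
   overall, except the presence/absence pattern (> 90 % missing in one
   group, < 10 % in the other), which is kept with zeros imputed in the
   high-missing group;
3. :func:`knn_impute` — k-nearest-neighbour imputation over protein rows
   (k = 3 by default);
4. :func:`log2_transform` — log2(x + 1) on the average-100 scale;
5. :func:`moderated_ttest` — two-group empirical-Bayes moderated t with
   Benjamini-Hochberg adjustment (:func:`bh_adjust`).

:func:`pca_retain` provides the sample-space PCA with the cumulative
>= 90 %-variance retention rule used for quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.decomposition import PCA
from sklearn.metrics.pairwise import nan_euclidean_distances
from statsmodels.stats.multitest import multipletests

MatrixLike = Union["AbundanceMatrix", pd.DataFrame]


@dataclass
class AbundanceMatrix:
    """Proteins x samples intensity table with a two-group annotation.

    ``data`` holds nonnegative peak areas with NaN marking missing values;
    ``groups`` maps each sample id to its group label.
    """

    data: pd.DataFrame
    groups: pd.Series
    log_scale: bool = False  # log2-transformed values may be negative

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("protein ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("sample ids must be unique")
        if list(self.data.columns) != list(self.groups.index):
            raise ValueError("groups index must match the sample columns")
        if not self.log_scale:
            vals = self.data.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError(
                    "intensities must be nonnegative where present")

    @property
    def group_names(self) -> list[str]:
        return list(pd.unique(self.groups))

    def group_columns(self, name: str) -> pd.Index:
        return self.groups.index[self.groups == name]

    def with_data(self, data: pd.DataFrame,
                  log_scale: bool = None) -> "AbundanceMatrix":
        return AbundanceMatrix(
            data=data, groups=self.groups.copy(),
            log_scale=self.log_scale if log_scale is None else log_scale,
        )


@dataclass
class FilterRule:
    """Missing-value filter thresholds (strict inequalities)."""

    overall_missing_max: float = 0.30
    group_high_missing_min: float = 0.90
    group_low_missing_max: float = 0.10

    def __post_init__(self) -> None:
        for name in ("overall_missing_max", "group_high_missing_min",
                     "group_low_missing_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.group_low_missing_max >= self.group_high_missing_min:
            raise ValueError("group_low_missing_max must be below "
                             "group_high_missing_min")


@dataclass
class DEResult:
    """Differential-abundance table plus the shrinkage prior.

    ``table`` has one row per tested protein: log2_fc (group2 - group1),
    moderated_t, p_value, bh_adjusted_p and filter_status.
    """

    table: pd.DataFrame
    df_prior: float
    s2_prior: float
    group_order: tuple[str, str]
    dropped: pd.Index = field(default_factory=lambda: pd.Index([]))


def _two_groups(am: AbundanceMatrix) -> tuple[str, str]:
    names = am.group_names
    if len(names) != 2:
        raise ValueError(f"exactly two groups required, got {names}")
    return names[0], names[1]


def normalize_abundance(am: AbundanceMatrix) -> AbundanceMatrix:
    """Total-peak-area normalization, grand mean of observed values = 100.

    Each sample's observed intensities are divided by that sample's total
    observed peak area, then one global constant rescales the matrix so
    the mean over all observed cells equals 100.  Missing cells stay
    missing.  Idempotent up to float tolerance.
    """
    X = am.data.to_numpy(dtype=float)
    totals = np.nansum(X, axis=0)
    dead = np.where(~(totals > 0))[0]
    if dead.size:
        raise ValueError(
            "sample(s) with no observed values: "
            + ", ".join(am.data.columns[dead])
        )
    X = X / totals[None, :]
    X = X * (100.0 / np.nanmean(X))
    return am.with_data(pd.DataFrame(X, index=am.data.index,
                                     columns=am.data.columns))


def filter_missing(
    am: AbundanceMatrix,
    rule: FilterRule = FilterRule(),
) -> tuple[AbundanceMatrix, pd.Series]:
    """Apply the missing-value filter with the presence/absence exception.

    A protein is dropped iff its overall missing fraction exceeds
    ``overall_missing_max`` and it does not match the exception
    (one group > ``group_high_missing_min`` missing while the other is
    < ``group_low_missing_max``).  Exception proteins are kept with the
    high-missing group's cells set to 0 (status ``kept_zero_imputed``);
    everything else is kept unchanged (status ``kept``).
    """
    g1, g2 = _two_groups(am)
    c1, c2 = am.group_columns(g1), am.group_columns(g2)
    miss = am.data.isna()
    f_all = miss.mean(axis=1)
    f1 = miss[c1].mean(axis=1)
    f2 = miss[c2].mean(axis=1)

    hi, lo = rule.group_high_missing_min, rule.group_low_missing_max
    exc_g1_high = (f1 > hi) & (f2 < lo)
    exc_g2_high = (f2 > hi) & (f1 < lo)
    exception = exc_g1_high | exc_g2_high
    dropped = (f_all > rule.overall_missing_max) & ~exception

    status = pd.Series("kept", index=am.data.index, name="filter_status")
    status[exception] = "kept_zero_imputed"
    status[dropped] = "dropped"

    out = am.data.loc[~dropped].copy()
    zi1 = exc_g1_high[~dropped]
    zi2 = exc_g2_high[~dropped]
    out.loc[zi1[zi1].index, c1] = out.loc[zi1[zi1].index, c1].fillna(0.0)
    out.loc[zi2[zi2].index, c2] = out.loc[zi2[zi2].index, c2].fillna(0.0)
    return am.with_data(out), status


def _knn_impute_array(X: np.ndarray, k: int) -> np.ndarray:
    """KNN imputation over rows; see :func:`knn_impute`."""
    n_rows = X.shape[0]
    if k < 1 or k >= n_rows:
        raise ValueError(f"k must satisfy 1 <= k < n_proteins, got k={k}")
    out = X.copy()
    miss = np.isnan(X)
    if not miss.any():
        return out
    if miss.all(axis=1).any():
        raise ValueError("cannot impute a protein with no observed values")
    # pairwise Euclidean distance over co-observed samples, scaled by
    # sqrt(n_samples / n_shared); pairs with no shared samples -> NaN
    D = nan_euclidean_distances(X, X)
    np.fill_diagonal(D, np.inf)
    D[np.isnan(D)] = np.inf
    order = np.argsort(D, axis=1, kind="stable")
    for i in np.nonzero(miss.any(axis=1))[0]:
        ranked = order[i][np.isfinite(D[i, order[i]])]
        for j in np.nonzero(miss[i])[0]:
            donors = ranked[~miss[ranked, j]][:k]
            if donors.size:
                out[i, j] = X[donors, j].mean()
            else:
                out[i, j] = np.nanmean(X[i])  # no eligible neighbour
    return out


def knn_impute(matrix: MatrixLike, k: int = 3) -> MatrixLike:
    """Impute remaining missing cells from the k nearest protein rows.

    Neighbours are ranked by Euclidean distance over co-observed samples
    (scaled by sqrt(n_samples / n_shared)); a missing cell receives the
    mean of the k nearest proteins observed in that sample.  A protein
    with no eligible neighbour falls back to its own observed mean.
    """
    df = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    imputed = pd.DataFrame(
        _knn_impute_array(df.to_numpy(dtype=float), k),
        index=df.index, columns=df.columns,
    )
    if isinstance(matrix, AbundanceMatrix):
        return matrix.with_data(imputed)
    return imputed


def log2_transform(matrix: MatrixLike, pseudocount: float = 1.0) -> MatrixLike:
    """x -> log2(x + pseudocount); zero-imputed cells map to 0 at the
    default pseudocount of 1 on the average-100 scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    df = matrix.data if isinstance(matrix, AbundanceMatrix) else matrix
    vals = df.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("negative intensity encountered")
    out = pd.DataFrame(np.log2(vals + pseudocount),
                       index=df.index, columns=df.columns)
    if isinstance(matrix, AbundanceMatrix):
        return matrix.with_data(out, log_scale=True)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance
    prior (df_prior, s2_prior) from the log sample variances."""
    z = np.log(s2[s2 > 0])
    if z.size == 0:
        raise ValueError("all proteins have zero variance (degenerate prior)")
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    if z.size < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1))
    diff = evar - float(special.polygamma(1, d / 2.0))
    if diff <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(diff)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_ttest(matrix_log2: AbundanceMatrix) -> DEResult:
    """Two-group empirical-Bayes moderated t-test with BH adjustment.

    Per protein: ``log2_fc = mean(group2) - mean(group1)``; the pooled
    residual variance s^2 (d = n1 + n2 - 2 df) is shrunk toward a prior
    s0^2 with d0 df estimated across proteins by moments of log s^2, giving
    ``s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)``.  The moderated t uses
    s_tilde and is referred to a t distribution with d0 + d degrees of
    freedom; two-sided p-values are BH-adjusted.
    """
    g1, g2 = _two_groups(matrix_log2)
    c1 = matrix_log2.group_columns(g1)
    c2 = matrix_log2.group_columns(g2)
    n1, n2 = len(c1), len(c2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    X = matrix_log2.data.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("moderated_ttest requires a complete matrix "
                         "(impute first)")
    X1 = matrix_log2.data[c1].to_numpy(dtype=float)
    X2 = matrix_log2.data[c2].to_numpy(dtype=float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    d = n1 + n2 - 2
    ss = X1.var(axis=1, ddof=1) * (n1 - 1) + X2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d

    d0, s02 = _fit_variance_prior(s2, d)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d
    fc = m2 - m1
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = fc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    table = pd.DataFrame(
        {
            "log2_fc": fc,
            "moderated_t": tstat,
            "p_value": p,
            "bh_adjusted_p": bh_adjust(p),
            "s2_posterior": s2_post,
        },
        index=matrix_log2.data.index,
    )
    return DEResult(table=table, df_prior=float(d0), s2_prior=float(s02),
                    group_order=(g1, g2))


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # proteins x components
    variance_fractions: np.ndarray
    n_retained: int


def pca_retain(matrix_log2: MatrixLike,
               variance_threshold: float = 0.90) -> PCAResult:
    """Sample-space PCA with cumulative-variance component retention.

    Proteins are centered, samples decomposed; ``n_retained`` is the
    smallest number of components whose cumulative variance fraction
    reaches ``variance_threshold`` (the >= 90 %-variability scree rule).
    """
    df = matrix_log2.data if isinstance(matrix_log2, AbundanceMatrix) \
        else matrix_log2
    if df.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if df.isna().any().any():
        raise ValueError("PCA requires a complete matrix")
    X = df.to_numpy(dtype=float).T  # samples x proteins
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    n_ret = int(np.searchsorted(np.cumsum(frac), variance_threshold) + 1)
    n_ret = min(n_ret, n_comp)
    comp_ids = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=df.columns, columns=comp_ids),
        loadings=pd.DataFrame(pca.components_.T, index=df.index,
                              columns=comp_ids),
        variance_fractions=frac,
        n_retained=n_ret,
    )


def differential_abundance_pipeline(
    am: AbundanceMatrix,
    rule: FilterRule = FilterRule(),
    k: int = 3,
    pseudocount: float = 1.0,
) -> DEResult:
    """Full chain: normalize -> filter/zero-impute -> KNN impute -> log2 ->
    moderated t -> BH.  The filter status of every input protein is merged
    into the result table (dropped proteins keep NaN statistics)."""
    normed = normalize_abundance(am)
    filtered, status = filter_missing(normed, rule)
    imputed = knn_impute(filtered, k=k)
    logged = log2_transform(imputed, pseudocount=pseudocount)
    res = moderated_ttest(logged)
    table = res.table.reindex(am.data.index)
    table["filter_status"] = status
    res.table = table
    res.dropped = status.index[status == "dropped"]
    return res
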