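"""Correlation, paired t-tests and PCA over the survey concentration matrix.

Non-detects enter as zeros, consistent with how the concentration table stores
them, so correlations reflect the reported data rather than an imputation
model.  The paired t-test exposes a degrees-of-freedom convention switch:
survey reports in this field sometimes quote the regression-style ``n − 2``
critical value (2.715 at alpha = 0.01 for 39 paired observations) instead of
the textbook ``n − 1``; both are supported, with ``n − 2`` the default.

PCA is the scikit-learn pipeline practitioners use directly: columns
standardized to zero mean and unit variance, then an SVD decomposition keeping
the smallest number of components reaching the requested cumulative explained
variance (90% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .sample_io import SampleTable

__all__ = ["CorrelationResult", "PairedTResult", "PCAResult",
           "pearson_matrix", "paired_t", "run_pca", "joint_index_correlation"]


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame  # symmetric Pearson r
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # pairs columns: var_a, var_b, r, t_statistic, p_value, df, t_critical


@dataclass
class PairedTResult:
    t_statistic: float
    p_value: float
    df: int
    t_critical: float
    alpha: float
    reject: bool
    overflow: bool = False


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # element × component, orthonormal columns
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame  # site × component
    n_components: int
    dropped: list[str] = field(default_factory=list)


def _corr_frame(frame: pd.DataFrame) -> pd.DataFrame:
    constant = frame.columns[frame.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(f"zero-variance columns have undefined correlations: {constant}")
    matrix = frame.corr(method="pearson")  # pandas leaves NaN for zero variance
    np.fill_diagonal(matrix.values, 1.0)
    return matrix


def pearson_matrix(table: SampleTable) -> CorrelationResult:
    """Pairwise Pearson correlations between element concentrations."""
    if table.n_sites < 3:
        raise ValueError("correlation needs at least 3 sites")
    return CorrelationResult(matrix=_corr_frame(table.conc))


def paired_t(
    x,
    y,
    df_convention: str = "n_minus_2",
    alpha: float = 0.01,
) -> PairedTResult:
    """Two-tailed paired t-test, ``t = mean(d) / (sd(d)/√n)`` with d = x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("paired_t needs two equal-length 1-D samples, n >= 3")
    n = len(x)
    if df_convention == "n_minus_2":
        df = n - 2
    elif df_convention == "n_minus_1":
        df = n - 1
    else:
        raise ValueError(f"unknown df convention {df_convention!r}")
    d = x - y
    sd = d.std(ddof=1)
    t_critical = float(stats.t.ppf(1 - alpha / 2, df))
    if sd == 0:
        if d.mean() == 0:
            return PairedTResult(0.0, 1.0, df, t_critical, alpha, reject=False)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTResult(t, 0.0, df, t_critical, alpha, reject=True, overflow=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df))
    return PairedTResult(t, p, df, t_critical, alpha, reject=abs(t) > t_critical)


def correlation_with_tests(
    table: SampleTable,
    pairs: list[tuple[str, str]] | None = None,
    df_convention: str = "n_minus_2",
    alpha: float = 0.01,
) -> CorrelationResult:
    """Correlation matrix plus paired-t results for selected element pairs."""
    result = pearson_matrix(table)
    rows = []
    for a, b in pairs or []:
        t_res = paired_t(table.conc[a], table.conc[b], df_convention, alpha)
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "r": result.matrix.loc[a, b],
                "t_statistic": t_res.t_statistic,
                "p_value": t_res.p_value,
                "df": t_res.df,
                "t_critical": t_res.t_critical,
            }
        )
    result.pairs = pd.DataFrame(rows)
    return result


def run_pca(table: SampleTable, variance_target: float = 0.90) -> PCAResult:
    """Standardized PCA keeping the fewest components reaching the target.

    Constant columns carry no variance and are dropped (with a warning)
    before standardization.
    """
    if table.n_sites < 3:
        raise ValueError("PCA needs at least 3 sites")
    conc = table.conc
    constant = conc.columns[conc.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(f"dropping constant columns before PCA: {constant}")
        conc = conc.drop(columns=constant)
    standardized = StandardScaler().fit_transform(conc.to_numpy(dtype=float))
    pca = PCA()
    scores = pca.fit_transform(standardized)
    ratios = pca.explained_variance_ratio_
    n_components = int(np.searchsorted(np.cumsum(ratios), variance_target) + 1)
    n_components = min(n_components, len(ratios))
    names = [f"PC{i + 1}" for i in range(len(ratios))]
    return PCAResult(
        loadings=pd.DataFrame(pca.components_.T, index=conc.columns, columns=names),
        explained_variance_ratio=ratios,
        scores=pd.DataFrame(scores, index=conc.index, columns=names),
        n_components=n_components,
        dropped=constant,
    )


def joint_index_correlation(
    pca: PCAResult,
    index_table: pd.DataFrame,
    table: SampleTable,
    index_columns: tuple[str, ...] = ("pli", "zc", "b_score"),
) -> CorrelationResult:
    """Correlation over coordinates, concentrations, indices and PC scores.

    This is the source-attribution view: it shows which principal components
    (element groupings) drive each aggregate pollution index.
    """
    if not table.frame.index.equals(index_table.index) or not table.frame.index.equals(
        pca.scores.index
    ):
        raise ValueError("site sets of table, indices and PCA scores must match")
    retained = pca.scores.iloc[:, : pca.n_components]
    joint = pd.concat(
        [table.frame[["x", "y"]], table.conc, index_table[list(index_columns)], retained],
        axis=1,
    )
    return CorrelationResult(matrix=_corr_frame(joint))
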