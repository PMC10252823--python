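"""Environmental and isotope-value comparisons.

Rank-based group comparisons (tie-corrected Kruskal-Wallis H with Dunn's
post-hoc z tests under Bonferroni correction), Pearson correlation, and a
correlation-matrix PCA of log10(x+1)-transformed environmental variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "KruskalResult", "DunnResult", "PcaResult", "kruskal_wallis",
    "dunn_bonferroni", "pca_correlation", "pearson_correlation",
]


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float
    tie_corrected: bool
    degenerate: bool = False


@dataclass(frozen=True)
class DunnResult:
    # (group_i, group_j, z, p_raw, p_bonferroni) per pair
    pairs: list


@dataclass
class PcaResult:
    loadings: pd.DataFrame        # variables x components (unit-norm)
    variance_explained: np.ndarray  # percent per component, sums to 100
    scores: np.ndarray            # samples x components
    important_variables: dict     # component -> [variables, |loading|>thr]


def kruskal_wallis(*groups) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value.

    Accepts either separate group vectors or a single iterable of vectors.
    All-identical data across groups yields H = 0 flagged degenerate.
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise InputError("kruskal_wallis: need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 1 for a in arrays):
        raise InputError("kruskal_wallis: every group needs >= 1 value")
    pooled = np.concatenate(arrays)
    if len(pooled) < 3:
        raise InputError("kruskal_wallis: need >= 3 values in total")
    df = len(arrays) - 1
    ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return KruskalResult(h=0.0, df=df, p=1.0, tie_corrected=ties,
                             degenerate=True)
    h, p = stats.kruskal(*arrays)
    return KruskalResult(h=float(h), df=df, p=float(p), tie_corrected=ties)


def dunn_bonferroni(*groups, labels=None) -> DunnResult:
    """Dunn's post-hoc pairwise z tests with Bonferroni correction.

    Uses the pooled ranking shared with the Kruskal-Wallis statistic and
    the tie term sum(t^3 - t):

        z_ij = (Rbar_i - Rbar_j)
               / sqrt((N(N+1)/12 - sumT/(12(N-1))) (1/n_i + 1/n_j))

    Two-sided p-values from the standard Normal; Bonferroni over all
    k(k-1)/2 pairs.
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InputError("dunn_bonferroni: need >= 2 groups")
    if any(len(a) == 0 for a in arrays):
        raise InputError("dunn_bonferroni: empty group")
    if labels is None:
        labels = [f"group_{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    rank_groups = np.split(ranks, np.cumsum([len(a) for a in arrays])[:-1])
    rbar = [rg.mean() for rg in rank_groups]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    base_var = (n_total * (n_total + 1) / 12.0
                - tie_term / (12.0 * (n_total - 1)))
    m = len(arrays) * (len(arrays) - 1) // 2
    pairs = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(base_var * (1.0 / len(arrays[i])
                                     + 1.0 / len(arrays[j])))
            z = 0.0 if se == 0 else (rbar[i] - rbar[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            pairs.append((labels[i], labels[j], float(z), float(p_raw),
                          float(min(1.0, p_raw * m))))
    return DunnResult(pairs=pairs)


def pearson_correlation(x, y):
    """Sample Pearson r with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("pearson_correlation: need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("pearson_correlation: zero-variance series")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def pca_correlation(env: pd.DataFrame, loading_threshold: float = 0.6,
                    log_transform: bool = True,
                    exclude_from_log=()) -> PcaResult:
    """Correlation-matrix PCA of (log-transformed) environmental variables.

    Numeric columns are log10(x+1)-transformed (unless listed in
    ``exclude_from_log``), standardized, and the correlation matrix
    eigen-decomposed.  Variance explained is reported in percent; loading
    columns are unit-norm eigenvectors oriented so each column's
    largest-magnitude element is positive.  Constant variables are removed
    with a warning.
    """
    data = env.select_dtypes(include=[np.number]).copy()
    for meta in ("site",):
        data = data.drop(columns=[c for c in data.columns if c == meta])
    if data.isna().any().any():
        raise InputError("pca_correlation: missing values not allowed")
    if data.shape[0] < 3 or data.shape[1] < 2:
        raise InputError("pca_correlation: need >= 3 samples and >= 2 "
                         "variables")
    if log_transform:
        for col in data.columns:
            if col not in exclude_from_log:
                if (data[col] <= -1).any():
                    raise InputError(
                        f"pca_correlation: column {col!r} has values <= -1,"
                        " log10(x+1) undefined")
                data[col] = np.log10(data[col] + 1.0)
    constant = [c for c in data.columns if data[c].nunique() == 1]
    if constant:
        warnings.warn(f"pca_correlation: constant variables removed: "
                      f"{constant}", stacklevel=2)
        data = data.drop(columns=constant)
    if data.shape[1] < 2:
        raise InputError("pca_correlation: fewer than 2 non-constant "
                         "variables")
    values = data.to_numpy(dtype=float)
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    corr = np.corrcoef(values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # sign convention: orient each component so its largest |loading| is +
    for j in range(eigvec.shape[1]):
        idx = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[idx, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    var_pct = 100.0 * eigval / eigval.sum()
    comp_names = [f"PC{j + 1}" for j in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=data.columns, columns=comp_names)
    scores = z @ eigvec
    important = {
        name: list(loadings.index[np.abs(loadings[name])
                                  > loading_threshold])
        for name in comp_names
    }
    return PcaResult(loadings=loadings, variance_explained=var_pct,
                     scores=scores, important_variables=important)
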