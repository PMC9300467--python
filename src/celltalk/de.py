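"""One-vs-all differential testing shared by gene expression, regulon
activity and motif-deviation analyses.

The test is a one-sided Wilcoxon rank-sum ("is the feature stochastically
greater in the in-group than in the pooled remainder?"), with an exact
null distribution for small tie-free samples and a tie-corrected,
continuity-corrected normal approximation otherwise.  Multiple-testing
correction is Bonferroni by default, Benjamini-Hochberg selectable;
correction is applied per group across features.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

ADJUST_METHODS = {"bonferroni": "bonferroni", "bh": "fdr_bh"}


def wilcoxon_one_sided(x, y, exact_limit: int = 10) -> tuple[float, float]:
    """One-sided rank-sum test that ``x`` is stochastically greater than ``y``.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic computed with
    midranks.  The p-value is exact (enumeration over rank splits) when
    ``len(x) + len(y) <= exact_limit`` and there are no ties, otherwise a
    normal approximation with tie correction and continuity correction.
    A fully degenerate comparison (zero rank variance) returns p = 0.5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_one_sided requires non-empty samples")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= exact_limit and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = stats.rankdata(pooled)
    u = ranks[:n].sum() - n * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    N = n + m
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return float(u), 0.5  # all observations tied: symmetric null
    z = (u - n * m / 2.0 - 0.5) / np.sqrt(var)
    return float(u), float(stats.norm.sf(z))


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment, order-preserving, output in (0, 1]."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, p_adj, _, _ = multipletests(p, method=ADJUST_METHODS[method])
    return p_adj


def log2_fold_change(norm_in, norm_out, pseudocount: float = 1.0,
                     mode: str = "expm1") -> float:
    """Effect size between two groups of normalized values.

    mode="expm1" (default): log2 of the ratio of group means on the
    de-logged (expm1) scale, each plus ``pseudocount`` — the convention
    used for log-normalized expression.  mode="meandiff": plain
    difference of group means, appropriate for signed z-score matrices
    where a ratio is undefined.
    """
    norm_in = np.asarray(norm_in, dtype=float)
    norm_out = np.asarray(norm_out, dtype=float)
    if mode == "expm1":
        a = np.expm1(norm_in).mean() + pseudocount
        b = np.expm1(norm_out).mean() + pseudocount
        return float(np.log2(a / b))
    if mode == "meandiff":
        return float(norm_in.mean() - norm_out.mean())
    raise ValueError(f"unknown fold-change mode {mode!r}")


def _tie_terms(X: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied groups (for rank variance)."""
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        out[j] = np.sum(counts**3 - counts)
    return out


class WilcoxonOneVsAll(BaseEstimator):
    """One-vs-all Wilcoxon rank-sum marker test over a cells x features matrix.

    For each group of cells, every feature is tested against the pooled
    remaining cells (alternative: greater in the group).  Because the
    pooled ranks of a feature do not depend on which group is in focus,
    ranks and tie corrections are computed once per feature and reused
    across groups, making the full sweep a handful of matrix products.

    Parameters
    ----------
    adjust : "bonferroni" or "bh"
        Per-group multiple-testing correction across features.
    fc_mode : "expm1" or "meandiff"
        Fold-change convention, see :func:`log2_fold_change`.
    pseudocount : float
        Pseudocount for the expm1 fold change.
    min_cells : int
        Groups smaller than this are skipped with a warning.
    exact_limit : int
        Use the exact rank-split enumeration when the total number of
        cells is at most this and the feature has no ties.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per (feature, group) with log2fc, p_raw, p_adj,
        frac_in, frac_out, n_in, n_out.
    """

    def __init__(self, adjust: str = "bonferroni", fc_mode: str = "expm1",
                 pseudocount: float = 1.0, min_cells: int = 3,
                 exact_limit: int = 10):
        self.adjust = adjust
        self.fc_mode = fc_mode
        self.pseudocount = pseudocount
        self.min_cells = min_cells
        self.exact_limit = exact_limit

    def fit(self, X, y, feature_names=None):
        """Run the one-vs-all sweep.

        X : (n_cells, n_features) array-like (dense or sparse),
        y : per-cell group labels.
        """
        if sp.issparse(X):
            X = np.asarray(X.todense())
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_cells, n_features = X.shape
        if y.shape[0] != n_cells:
            raise ValueError("labels length does not match number of cells")
        groups = sorted(pd.unique(y).tolist())
        if len(groups) < 2:
            raise ValueError("one-vs-all testing requires at least 2 groups")
        if feature_names is None:
            feature_names = [f"feature_{j}" for j in range(n_features)]

        ranks = stats.rankdata(X, axis=0)
        tie_terms = _tie_terms(X)
        detected = X > 0
        expm1 = np.expm1(X) if self.fc_mode == "expm1" else None

        frames = []
        N = n_cells
        for g in groups:
            mask = y == g
            n1 = int(mask.sum())
            n2 = N - n1
            if n1 < self.min_cells:
                warnings.warn(
                    f"group {g!r} has {n1} cells (< {self.min_cells}); skipped"
                )
                continue
            r1 = ranks[mask].sum(axis=0)
            u = r1 - n1 * (n1 + 1) / 2.0
            var = n1 * n2 / 12.0 * ((N + 1) - tie_terms / (N * (N - 1)))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (u - n1 * n2 / 2.0 - 0.5) / np.sqrt(var)
            p = stats.norm.sf(z)
            p = np.where(var <= 0, 0.5, p)
            if N <= self.exact_limit:
                # small-sample path: defer to the exact/scalar routine
                for j in range(n_features):
                    u_j, p_j = wilcoxon_one_sided(
                        X[mask, j], X[~mask, j], exact_limit=self.exact_limit
                    )
                    u[j], p[j] = u_j, p_j
            p = np.clip(p, np.finfo(float).tiny, 1.0)
            if self.fc_mode == "expm1":
                mean_in = expm1[mask].mean(axis=0) + self.pseudocount
                mean_out = expm1[~mask].mean(axis=0) + self.pseudocount
                lfc = np.log2(mean_in / mean_out)
            else:
                lfc = X[mask].mean(axis=0) - X[~mask].mean(axis=0)
            frames.append(pd.DataFrame({
                "feature": feature_names,
                "group": g,
                "log2fc": lfc,
                "p_raw": p,
                "p_adj": adjust_pvalues(p, self.adjust),
                "frac_in": detected[mask].mean(axis=0),
                "frac_out": detected[~mask].mean(axis=0),
                "n_in": n1,
                "n_out": n2,
            }))
        if not frames:
            raise ValueError("no group reached min_cells; nothing tested")
        self.results_ = pd.concat(frames, ignore_index=True)
        self.groups_ = groups
        return self

    def fit_predict(self, X, y, feature_names=None) -> pd.DataFrame:
        return self.fit(X, y, feature_names=feature_names).results_


def de_one_vs_all(matrix, labels, feature_names=None, *,
                  adjust: str = "bonferroni", fc_mode: str = "expm1",
                  pseudocount: float = 1.0, min_cells: int = 3,
                  exact_limit: int = 10) -> pd.DataFrame:
    """Functional wrapper over :class:`WilcoxonOneVsAll`.

    ``matrix`` is features x cells (the tabular orientation used by the
    pipeline's intermediate files); it is transposed into the estimator's
    cells x features convention.
    """
    if sp.issparse(matrix):
        X = matrix.T
    else:
        X = np.asarray(matrix, dtype=float).T
    est = WilcoxonOneVsAll(adjust=adjust, fc_mode=fc_mode,
                           pseudocount=pseudocount, min_cells=min_cells,
                           exact_limit=exact_limit)
    return est.fit_predict(X, labels, feature_names=feature_names)
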