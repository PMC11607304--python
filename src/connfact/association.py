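"""Factor-expression / clinical-score association statistics.

Covers covariate residualization, the scalar-side CCA (equivalent to a
multiple-correlation problem because the factor side is 1-dimensional),
site-aware permutation testing, Benjamini-Hochberg FDR, group and
longitudinal comparisons, and out-of-sample prediction-error summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "fdr_adjust", "residualize", "CcaResult", "cca_factor_scale",
    "permutation_p", "cca_permutation", "run_cca_suite", "group_compare",
    "paired_change_test", "change_association", "prediction_error",
]


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, m * p_(j) / j) over the sorted p-values.
    """
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    m = flat.size
    if m == 0:
        return p.copy()
    if np.any((flat < 0) | (flat > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(flat, kind="stable")
    ranked = flat[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q.reshape(p.shape)


def _build_design(n: int, covariates: np.ndarray | None = None,
                  site_labels: Sequence | None = None) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates + one-hot sites (reference level dropped)."""
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float).reshape(n, -1)
        for j in range(c.shape[1]):
            cols.append(c[:, j])
            names.append(f"cov{j}")
    if site_labels is not None:
        sites = pd.Series(list(site_labels))
        levels = sites.unique()
        for lv in levels[1:]:
            cols.append((sites == lv).to_numpy(dtype=float))
            names.append(f"site[{lv}]")
    return np.column_stack(cols), names


def residualize(values: np.ndarray, covariates: np.ndarray | None = None,
                site_labels: Sequence | None = None) -> np.ndarray:
    """OLS residuals of each column of ``values`` on intercept +
    covariates (+ one-hot sites).

    Raises
    ------
    ValueError
        On rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    squeeze = y.ndim == 1
    y = y.reshape(y.shape[0], -1)
    n = y.shape[0]
    x, names = _build_design(n, covariates, site_labels)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # pivoted QR flags which columns are linearly dependent
        from scipy.linalg import qr
        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag))
               if diag[i] < 1e-10 * diag[0]] or [names[piv[rank]]]
        raise ValueError(f"collinear covariate columns: {bad}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return resid[:, 0] if squeeze else resid


@dataclass
class CcaResult:
    """One factor x clinical-scale canonical-correlation result."""

    factor: int | str
    scale: str
    r: float
    weights: np.ndarray
    structural_coefs: np.ndarray
    n: int
    p: float | None = None
    q: float | None = None
    item_names: list = field(default_factory=list)


def _multiple_correlation(loading: np.ndarray, items: np.ndarray
                          ) -> tuple[float, np.ndarray, np.ndarray]:
    """First canonical pair for a scalar left side: regress loading on
    items; r = corr(loading, fitted); structural coefficient = per-item
    correlation with the fitted clinical variate."""
    n, p = items.shape
    x = np.column_stack([np.ones(n), items])
    coef, *_ = np.linalg.lstsq(x, loading, rcond=None)
    fitted = x @ coef
    fc = fitted - fitted.mean()
    lc = loading - loading.mean()
    denom = np.linalg.norm(fc) * np.linalg.norm(lc)
    r = float(fc @ lc / denom) if denom > 0 else 0.0
    # sign convention: canonical variate positively correlated with loading
    weights = coef[1:]
    if r < 0:  # cannot happen for OLS fitted values, kept for safety
        weights, fc, r = -weights, -fc, -r
    ic = items - items.mean(axis=0)
    inorm = np.linalg.norm(ic, axis=0) * np.linalg.norm(fc)
    struct = np.where(inorm > 0, ic.T @ fc / np.where(inorm > 0, inorm, 1.0), 0.0)
    return r, weights, struct


def cca_factor_scale(loading: np.ndarray, items: np.ndarray,
                     covariates: np.ndarray | None = None,
                     site_labels: Sequence | None = None,
                     factor: int | str = 0, scale: str = "scale",
                     item_names: Sequence[str] | None = None) -> CcaResult:
    """CCA between one factor's loadings and one scale's item scores.

    Both sides are residualized on covariates/sites first.  Because the
    factor side is scalar, the first canonical correlation equals the
    multiple correlation of regressing the loading on the items.
    """
    y = np.asarray(loading, dtype=float).ravel()
    x = np.asarray(items, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError("loading and items disagree on n")
    n_cov = 0 if covariates is None else np.asarray(covariates).reshape(n, -1).shape[1]
    if p >= n:
        raise ValueError(
            f"{p} items with only {n} subjects: reduce the item set "
            "(no silent regularization is applied)")
    if n <= p + n_cov + 2:
        raise ValueError(
            f"n={n} too small for p={p} items and {n_cov} covariates")
    if covariates is not None or site_labels is not None:
        y = residualize(y, covariates, site_labels)
        x = residualize(x, covariates, site_labels)
    r, weights, struct = _multiple_correlation(y, x)
    return CcaResult(factor=factor, scale=scale, r=r, weights=weights,
                     structural_coefs=struct, n=n,
                     item_names=list(item_names) if item_names else
                     [f"item{j}" for j in range(p)])


def permutation_p(stat_fn: Callable[[np.ndarray], float], values: np.ndarray,
                  site_labels: Sequence | None = None, n_perm: int = 10000,
                  seed: int = 0) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of ``stat_fn`` with shuffling restricted to
    within-site blocks.

    Returns (observed statistic, p, null statistics).  p uses the
    add-one rule ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    v = np.asarray(values)
    n = v.shape[0]
    obs = float(stat_fn(v))
    rng = np.random.default_rng(seed)
    if site_labels is None:
        blocks = [np.arange(n)]
    else:
        sites = pd.Series(list(site_labels))
        blocks = [np.flatnonzero((sites == s).to_numpy()) for s in sites.unique()]
        singles = [s for s, b in zip(sites.unique(), blocks) if b.size < 2]
        if singles:
            warnings.warn(
                f"sites with < 2 subjects are fixed points under permutation: "
                f"{singles}", RuntimeWarning)
    null = np.empty(n_perm)
    perm = np.arange(n)
    for i in range(n_perm):
        for b in blocks:
            perm[b] = b[rng.permutation(b.size)]
        null[i] = stat_fn(v[perm])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return obs, float(p), null


def cca_permutation(loading: np.ndarray, items: np.ndarray,
                    covariates: np.ndarray | None = None,
                    site_labels: Sequence | None = None,
                    n_perm: int = 10000, seed: int = 0,
                    factor: int | str = 0, scale: str = "scale",
                    item_names: Sequence[str] | None = None) -> CcaResult:
    """:func:`cca_factor_scale` plus a site-aware permutation p-value.

    Covariates are residualized out once; the (residualized) loading
    vector is then permuted within site blocks, which keeps the
    clinical side and nuisance structure fixed.
    """
    res = cca_factor_scale(loading, items, covariates, site_labels,
                           factor=factor, scale=scale, item_names=item_names)
    y = np.asarray(loading, dtype=float).ravel()
    x = np.asarray(items, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if covariates is not None or site_labels is not None:
        y = residualize(y, covariates, site_labels)
        x = residualize(x, covariates, site_labels)
    # precompute an orthonormal basis of the item space: r is then a
    # projection norm, making each permutation O(n p)
    xc = x - x.mean(axis=0)
    qmat, _ = np.linalg.qr(xc)

    def stat(yperm: np.ndarray) -> float:
        yc = yperm - yperm.mean()
        nrm = np.linalg.norm(yc)
        if nrm == 0:
            return 0.0
        return float(np.linalg.norm(qmat.T @ yc) / nrm)

    _, p, _ = permutation_p(stat, y, site_labels, n_perm=n_perm, seed=seed)
    res.p = p
    return res


def run_cca_suite(loadings: pd.DataFrame, phenotypes: pd.DataFrame,
                  scales: Mapping[str, Sequence[str]],
                  covariate_cols: Sequence[str] = (),
                  site_col: str | None = None,
                  n_perm: int = 10000, seed: int = 0,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One CCA per (factor, scale) pair with BH-FDR across all pairs.

    ``loadings`` columns are factors, indexed like ``phenotypes``.
    Subjects missing any item of a scale are dropped listwise for that
    scale only.  Returns (tidy results, per-item structural
    coefficients).
    """
    results: list[CcaResult] = []
    rows_struct = []
    for s_i, (scale_name, item_cols) in enumerate(scales.items()):
        item_cols = list(item_cols)
        sub = phenotypes.dropna(subset=item_cols)
        idx = loadings.index.intersection(sub.index)
        sub = sub.loc[idx]
        items = sub[item_cols].to_numpy(dtype=float)
        covs = sub[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else None
        sites = sub[site_col] if site_col else None
        for f_i, factor in enumerate(loadings.columns):
            res = cca_permutation(
                loadings.loc[idx, factor].to_numpy(dtype=float), items,
                covariates=covs, site_labels=None if sites is None else sites.tolist(),
                n_perm=n_perm, seed=seed + 1009 * s_i + f_i,
                factor=factor, scale=scale_name, item_names=item_cols)
            results.append(res)
            for name, w, sc in zip(item_cols, res.weights, res.structural_coefs):
                rows_struct.append({"factor": factor, "scale": scale_name,
                                    "item": name, "weight": w,
                                    "structural_coef": sc})
    qs = fdr_adjust(np.array([r.p for r in results]))
    for r, q in zip(results, qs):
        r.q = float(q)
    tidy = pd.DataFrame([{"factor": r.factor, "scale": r.scale, "r": r.r,
                          "p": r.p, "q": r.q, "n": r.n} for r in results])
    return tidy, pd.DataFrame(rows_struct)


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact when sample sizes are small and there
    are no ties, otherwise the tie-corrected normal approximation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def group_compare(loadings: np.ndarray, group_labels: Sequence,
                  ) -> pd.DataFrame:
    """Per-factor two-sided Wilcoxon rank-sum comparison of two groups,
    BH-FDR across factors."""
    x = np.atleast_2d(np.asarray(loadings, dtype=float))
    labels = pd.Series(list(group_labels))
    levels = labels.unique()
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}")
    a_idx = (labels == levels[0]).to_numpy()
    rows = []
    for k in range(x.shape[1]):
        stat, p = _rank_sum_p(x[a_idx, k], x[~a_idx, k])
        med_diff = float(np.median(x[a_idx, k]) - np.median(x[~a_idx, k]))
        rows.append({"factor": k, "statistic": stat, "p": p,
                     "median_diff": med_diff})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def paired_change_test(pre: np.ndarray, post: np.ndarray,
                       method: str = "ranksum") -> pd.DataFrame:
    """Per-factor two-sided test of pre vs post expression.

    ``method="ranksum"`` treats pre and post as two samples (the
    default); ``method="signed_rank"`` runs the Wilcoxon signed-rank
    test on the paired differences.
    """
    a = np.atleast_2d(np.asarray(pre, dtype=float))
    b = np.atleast_2d(np.asarray(post, dtype=float))
    if a.shape != b.shape:
        raise ValueError("pre and post must have the same shape")
    rows = []
    for k in range(a.shape[1]):
        if method == "ranksum":
            stat, p = _rank_sum_p(a[:, k], b[:, k])
        elif method == "signed_rank":
            d = b[:, k] - a[:, k]
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                res = sps.wilcoxon(a[:, k], b[:, k], zero_method="wilcox")
                stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError("method must be 'ranksum' or 'signed_rank'")
        rows.append({"factor": k, "statistic": stat, "p": p,
                     "median_change": float(np.median(b[:, k] - a[:, k]))})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def change_association(delta_loading: np.ndarray, delta_symptom: np.ndarray,
                       covariates: np.ndarray | None = None,
                       site_labels: Sequence | None = None,
                       ) -> tuple[float, float]:
    """Spearman correlation between expression change and symptom
    change, both residualized on covariates first."""
    dl = np.asarray(delta_loading, dtype=float).ravel()
    ds = np.asarray(delta_symptom, dtype=float).ravel()
    if dl.shape != ds.shape:
        raise ValueError("delta vectors must have equal length")
    if covariates is not None or site_labels is not None:
        dl = residualize(dl, covariates, site_labels)
        ds = residualize(ds, covariates, site_labels)
    rho, p = sps.spearmanr(dl, ds)
    return float(rho), float(p)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def prediction_error(predicted: np.ndarray, scores: np.ndarray,
                     covariates: np.ndarray | None = None,
                     ) -> tuple[float, float]:
    """(MSE, Pearson r) between predicted factor expression and clinical
    scores.

    MSE is computed after min-max mapping both vectors to [0, 1] —
    loadings and raw clinical scores live on incommensurate scales, so
    the raw squared error would be meaningless; this normalization is a
    deliberate, documented convention.
    """
    y = np.asarray(predicted, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError("vectors must have equal length")
    ry, rs = y, s
    if covariates is not None:
        ry = residualize(y, covariates)
        rs = residualize(s, covariates)
    r = float(np.corrcoef(ry, rs)[0, 1]) if np.std(ry) > 0 and np.std(rs) > 0 else 0.0
    mse = float(np.mean((_minmax(y) - _minmax(s)) ** 2))
    return mse, r
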