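"""Connectivity matrices: construction, vectorization, reference
normalization and count encoding.

The processing chain is

    time series -> correlation matrix -> edge vector -> deviation vector
    (z units relative to a control reference) -> signed count document

Count documents are the observations consumed by
:mod:`connfact.lda`: each edge contributes one of two vocabulary words
(``edge+`` for hyper-connectivity, ``edge-`` for hypo-connectivity) with
a count proportional to the magnitude of its deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import Parcellation

_SYMMETRY_TOL = 1e-10


def edge_index(n_regions: int) -> np.ndarray:
    """(E, 2) array of 0-based (i, j) pairs, i < j, row-major over the
    strict upper triangle."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


def edge_labels(parcellation: Parcellation) -> list[str]:
    """``"regionA|regionB"`` labels in edge order."""
    idx = edge_index(parcellation.n_regions)
    rid = parcellation.region_ids
    return [f"{rid[i]}|{rid[j]}" for i, j in idx]


def compute_fc(timeseries: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of a T x R time-series array.

    Raises
    ------
    ValueError
        If T < 3 or any region has zero temporal variance (named in the
        message).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be T x R with T >= 3")
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s) at column(s) {dead.tolist()}")
    fc = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(fc, 1.0)
    return fc


def validate_connectivity(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("connectivity matrix must be square")
    if np.max(np.abs(m - m.T)) > _SYMMETRY_TOL:
        raise ValueError("connectivity matrix is not symmetric within tolerance")
    return m


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix into its strict upper triangle
    (row-major), length R(R-1)/2."""
    m = validate_connectivity(matrix)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu].copy()


def unvectorize(values: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize`; fills the diagonal with ``diagonal``."""
    v = np.asarray(values, dtype=float)
    e = v.shape[0]
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if r * (r - 1) // 2 != e:
        raise ValueError(f"length {e} is not a triangular number")
    m = np.full((r, r), diagonal, dtype=float)
    iu = np.triu_indices(r, k=1)
    m[iu] = v
    m[(iu[1], iu[0])] = v
    return m


def fisher_z(values: np.ndarray) -> np.ndarray:
    """Fisher r-to-z transform (arctanh), clipping to keep it finite."""
    return np.arctanh(np.clip(values, -0.999999, 0.999999))


@dataclass(frozen=True)
class ReferenceStats:
    """Per-edge OLS of edge value on covariates, fit on controls.

    ``coef`` is (C+1) x E with the intercept in row 0; ``resid_sd`` is
    the per-edge residual standard deviation (ddof = number of
    parameters).
    """

    coef: np.ndarray
    resid_sd: np.ndarray
    n_controls: int

    @property
    def n_covariates(self) -> int:
        return self.coef.shape[0] - 1

    def predict(self, covariates: np.ndarray | None) -> np.ndarray:
        design = _design_row(covariates, self.n_covariates)
        return design @ self.coef


def _design_row(covariates: np.ndarray | None, n_cov: int) -> np.ndarray:
    if n_cov == 0:
        if covariates is not None and np.size(covariates):
            raise ValueError("reference was fit without covariates")
        return np.ones(1)
    c = np.atleast_1d(np.asarray(covariates, dtype=float))
    if c.shape[0] != n_cov:
        raise ValueError(f"expected {n_cov} covariates, got {c.shape[0]}")
    return np.concatenate([[1.0], c])


def fit_reference(control_vectors: np.ndarray,
                  control_covariates: np.ndarray | None = None) -> ReferenceStats:
    """Fit the per-edge control reference (w-score regression).

    Parameters
    ----------
    control_vectors : (n, E) array
        One edge vector per control subject.
    control_covariates : (n, C) array, optional
        Nuisance covariates; omit for an intercept-only (mean/sd)
        reference.
    """
    y = np.atleast_2d(np.asarray(control_vectors, dtype=float))
    n = y.shape[0]
    if control_covariates is None or np.size(control_covariates) == 0:
        x = np.ones((n, 1))
    else:
        c = np.asarray(control_covariates, dtype=float)
        c = c.reshape(n, -1)
        x = np.column_stack([np.ones(n), c])
    p = x.shape[1]
    if n <= p:
        raise ValueError(f"need more than {p} controls to fit {p} parameters, got {n}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    resid_sd = np.sqrt((resid ** 2).sum(axis=0) / (n - p))
    if np.any(resid_sd < 1e-8):
        k = int(np.argmin(resid_sd))
        raise ValueError(f"degenerate reference: residual sd < 1e-8 at edge {k}")
    return ReferenceStats(coef=coef, resid_sd=resid_sd, n_controls=n)


def deviation_score(values: np.ndarray, covariates: np.ndarray | None,
                    reference: ReferenceStats) -> np.ndarray:
    """Covariate-adjusted z (w-score) of one subject's edge vector
    relative to the control reference."""
    v = np.asarray(values, dtype=float)
    pred = reference.predict(covariates)
    if v.shape != pred.shape:
        raise ValueError("edge vector length does not match reference")
    return (v - pred) / reference.resid_sd


@dataclass(frozen=True)
class CountDocument:
    """Nonnegative counts over the signed edge vocabulary
    ``[edge_1+ ... edge_E+, edge_1- ... edge_E-]``."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.shape[0] % 2:
            raise ValueError("counts must be a flat vector of even length 2E")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        e = c.shape[0] // 2
        if np.any((c[:e] > 0) & (c[e:] > 0)):
            raise ValueError("an edge cannot carry both signs")

    @property
    def n_edges(self) -> int:
        return self.counts.shape[0] // 2

    @property
    def total_tokens(self) -> int:
        return int(self.counts.sum())


def encode_counts(deviations: np.ndarray, scale: float = 10.0,
                  clip: float = 3.0) -> CountDocument:
    """Turn a deviation vector into a signed count document.

    z is clipped to [-clip, clip]; ``round(scale * |z|)`` tokens go to
    ``edge+`` when z > 0 and ``edge-`` when z < 0.
    """
    if scale <= 0 or clip <= 0:
        raise ValueError("scale and clip must be positive")
    z = np.clip(np.asarray(deviations, dtype=float), -clip, clip)
    mag = np.rint(scale * np.abs(z)).astype(np.int64)
    e = z.shape[0]
    counts = np.zeros(2 * e, dtype=np.int64)
    pos = z > 0
    neg = z < 0
    counts[:e][pos] = mag[pos]
    counts[e:][neg] = mag[neg]
    if counts.sum() == 0:
        raise ValueError("all counts are zero; increase `scale`")
    return CountDocument(counts=counts)


def signed_from_counts(counts: np.ndarray) -> np.ndarray:
    """Collapse a length-2E vector over the signed vocabulary into a
    length-E signed edge vector (positive mass minus negative mass)."""
    c = np.asarray(counts, dtype=float)
    e = c.shape[0] // 2
    return c[:e] - c[e:]


def write_edge_table(path, vectors: np.ndarray, subject_ids: Sequence[str],
                     parcellation: Parcellation) -> None:
    """Write an edges x subjects CSV with ``regionA|regionB`` row
    labels (one column per subject)."""
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    if v.shape[1] != parcellation.n_edges:
        raise ValueError("edge vector length does not match parcellation")
    pd.DataFrame(v.T, index=pd.Index(edge_labels(parcellation), name="edge"),
                 columns=list(subject_ids)).to_csv(path)


def network_block_summary(values: np.ndarray,
                          parcellation: Parcellation) -> pd.DataFrame:
    """Mean edge value per within/between-network block.

    Returns a symmetric networks x networks DataFrame; block (a, b) is
    the mean over edges with one endpoint in network a and the other in
    network b.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] != parcellation.n_edges:
        raise ValueError("edge vector length does not match parcellation")
    net = parcellation.network_indices()
    idx = edge_index(parcellation.n_regions)
    a = np.minimum(net[idx[:, 0]], net[idx[:, 1]])
    b = np.maximum(net[idx[:, 0]], net[idx[:, 1]])
    q = len(parcellation.networks)
    sums = np.zeros((q, q))
    cnts = np.zeros((q, q))
    np.add.at(sums, (a, b), v)
    np.add.at(cnts, (a, b), 1.0)
    # (a, b) only fills the upper triangle; mirror before averaging
    sums = sums + np.triu(sums, k=1).T
    cnts = cnts + np.triu(cnts, k=1).T
    with np.errstate(invalid="ignore"):
        block = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.DataFrame(block, index=parcellation.networks,
                        columns=parcellation.networks)


def network_distribution(values: np.ndarray,
                         parcellation: Parcellation) -> pd.Series:
    """Radar-style per-network score: row sums of block magnitudes,
    min-max scaled to [0, 1]."""
    block = network_block_summary(values, parcellation)
    score = np.abs(np.nan_to_num(block.to_numpy())).sum(axis=1)
    lo, hi = score.min(), score.max()
    scaled = np.zeros_like(score) if hi == lo else (score - lo) / (hi - lo)
    return pd.Series(scaled, index=parcellation.networks)


def block_edge_counts(parcellation: Parcellation) -> pd.DataFrame:
    """Number of edges per network block (companion to
    :func:`network_block_summary`)."""
    ones = np.ones(parcellation.n_edges)
    net = parcellation.network_indices()
    idx = edge_index(parcellation.n_regions)
    a = np.minimum(net[idx[:, 0]], net[idx[:, 1]])
    b = np.maximum(net[idx[:, 0]], net[idx[:, 1]])
    q = len(parcellation.networks)
    cnts = np.zeros((q, q))
    np.add.at(cnts, (a, b), ones)
    cnts = cnts + np.triu(cnts, k=1).T
    return pd.DataFrame(cnts, index=parcellation.networks,
                        columns=parcellation.networks)
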