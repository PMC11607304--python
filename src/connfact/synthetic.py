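"""Synthetic cohorts with planted latent-factor structure.

Every downstream stage (encoding, factor fitting, association testing,
Dice overlap) is testable against the ground truth produced here:
sparse signed factor profiles organised into network blocks, Dirichlet
subject mixtures, connectivity = mixture of profiles + Gaussian edge
noise relative to a control reference, symptom items linearly coupled
to chosen factor loadings, and pre/post-treatment pairs whose symptom
change tracks the change in one factor's expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .connectome import edge_index, unvectorize
from .parcellation import Parcellation

__all__ = [
    "ScaleCoupling", "GroundTruth", "generate_factor_profiles",
    "generate_edge_profiles", "sample_loadings", "sample_cohort",
    "sample_controls", "sample_phenotypes", "sample_longitudinal",
    "write_cohort",
]

_CLIP = 0.999  # keep correlations strictly inside (-1, 1) for Fisher z


@dataclass(frozen=True)
class ScaleCoupling:
    """Linear coupling of one clinical scale to factor loadings.

    ``couplings`` maps factor index -> (tuple of coupled item indices,
    effect size).  Items not referenced are pure noise.
    """

    n_items: int
    couplings: Mapping[int, tuple[tuple[int, ...], float]] = field(
        default_factory=dict)


@dataclass
class GroundTruth:
    """Planted parameters of a synthetic cohort."""

    factor_profiles: np.ndarray                 # (K, E) signed effects
    support_fraction: float
    parcellation: Parcellation | None = None
    subject_loadings: np.ndarray | None = None  # (N, K) simplex rows
    site_labels: list | None = None
    covariates: np.ndarray | None = None
    symptom_coupling: Mapping[str, ScaleCoupling] = field(default_factory=dict)
    treatment_effect: float = 0.0

    @property
    def n_factors(self) -> int:
        return self.factor_profiles.shape[0]

    @property
    def n_edges(self) -> int:
        return self.factor_profiles.shape[1]


def _draw_support(rng: np.random.Generator, weights: np.ndarray,
                  m: int) -> np.ndarray:
    """Weighted sampling without replacement via exponential keys."""
    keys = rng.exponential(size=weights.size) / weights
    return np.argsort(keys)[:m]


def generate_edge_profiles(K: int, n_edges: int, sparsity: float = 0.15,
                           seed: int = 0,
                           magnitude_range: tuple[float, float] = (0.6, 1.4),
                           max_overlap: float = 0.5,
                           weights: np.ndarray | None = None) -> np.ndarray:
    """Parcellation-free sparse signed profiles over an arbitrary edge
    count (the block-structured front end is
    :func:`generate_factor_profiles`)."""
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if weights is None:
        weights = np.ones(n_edges)
    m = max(1, int(round(sparsity * n_edges)))
    rng = np.random.default_rng(seed)
    for _ in range(200):
        supports = [_draw_support(rng, weights, m) for _ in range(K)]
        ok = all(
            np.intersect1d(supports[i], supports[j]).size < max_overlap * m
            for i in range(K) for j in range(i + 1, K))
        if ok:
            break
    else:
        raise RuntimeError(
            "could not draw factor supports with pairwise overlap below "
            f"{max_overlap:.0%}; lower sparsity or block_bias")
    profiles = np.zeros((K, n_edges))
    lo, hi = magnitude_range
    for k, sup in enumerate(supports):
        mag = rng.uniform(lo, hi, size=m)
        sign = rng.choice([-1.0, 1.0], size=m)
        profiles[k, sup] = sign * mag
    return profiles


def generate_factor_profiles(K: int, parcellation: Parcellation,
                             sparsity: float = 0.15, block_bias: float = 4.0,
                             seed: int = 0,
                             n_focus_blocks: int = 4) -> np.ndarray:
    """K sparse signed edge profiles whose support concentrates within a
    few randomly chosen network blocks.

    ``block_bias`` scales the sampling weight of edges inside each
    factor's focus blocks (0 means uniform across all edges); profiles
    carry both hyper (positive) and hypo (negative) entries and pairwise
    support overlap stays below 50%.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if block_bias < 0:
        raise ValueError("block_bias must be nonnegative")
    e = parcellation.n_edges
    net = parcellation.network_indices()
    idx = edge_index(parcellation.n_regions)
    a = np.minimum(net[idx[:, 0]], net[idx[:, 1]])
    b = np.maximum(net[idx[:, 0]], net[idx[:, 1]])
    q = len(parcellation.networks)
    block_id = a * q + b
    all_blocks = np.unique(block_id)

    rng = np.random.default_rng(seed)
    m = max(1, int(round(sparsity * e)))
    profiles = np.zeros((K, e))
    supports = []
    for _ in range(200):
        supports.clear()
        for _k in range(K):
            focus = rng.choice(all_blocks, size=min(n_focus_blocks,
                                                    all_blocks.size),
                               replace=False)
            w = 1.0 + block_bias * np.isin(block_id, focus)
            supports.append(_draw_support(rng, w, m))
        ok = all(
            np.intersect1d(supports[i], supports[j]).size < 0.5 * m
            for i in range(K) for j in range(i + 1, K))
        if ok:
            break
    else:
        raise RuntimeError("could not draw sufficiently disjoint supports; "
                           "lower sparsity")
    for k, sup in enumerate(supports):
        mag = rng.uniform(0.6, 1.4, size=m)
        sign = rng.choice([-1.0, 1.0], size=m)
        profiles[k, sup] = sign * mag
    return profiles


def sample_loadings(n: int, dirichlet_alpha: Sequence[float],
                    seed: int = 0) -> np.ndarray:
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("dirichlet_alpha must be positive")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(alpha, size=n)


def _deviations(loadings: np.ndarray, profiles: np.ndarray, noise_sd: float,
                rng: np.random.Generator) -> np.ndarray:
    return loadings @ profiles + rng.normal(0.0, noise_sd, size=(
        loadings.shape[0], profiles.shape[1]))


def _to_matrices(deviations: np.ndarray,
                 site_offsets: np.ndarray | None = None) -> list[np.ndarray]:
    dev = deviations if site_offsets is None else deviations + site_offsets
    dev = np.clip(dev, -_CLIP, _CLIP)
    return [unvectorize(row) for row in dev]


def timeseries_for_matrix(matrix: np.ndarray, n_timepoints: int,
                          rng: np.random.Generator) -> np.ndarray:
    """T x R Gaussian series whose population correlation equals the
    nearest positive-definite version of ``matrix``."""
    r = matrix.shape[0]
    if n_timepoints < r + 2:
        raise ValueError("n_timepoints must be >= R + 2")
    w, v = np.linalg.eigh((matrix + matrix.T) / 2)
    cov = (v * np.maximum(w, 1e-6)) @ v.T
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n_timepoints, r)) @ chol.T


def sample_cohort(truth: GroundTruth, n_subjects: int,
                  dirichlet_alpha: Sequence[float], noise_sd: float,
                  seed: int = 0, n_timepoints: int | None = None,
                  site_labels: Sequence | None = None,
                  site_effect_sd: float = 0.0,
                  ) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw a patient cohort from planted profiles.

    Each subject's edge deviation vector is
    ``sum_k loading_k * profile_k + N(0, noise_sd)``; returned matrices
    are symmetric with unit diagonal and off-diagonal entries clipped to
    (-0.999, 0.999).  Loadings (Dirichlet rows) are stored on ``truth``
    and returned.  With ``n_timepoints``, matrices are replaced by
    correlation matrices of simulated T x R time series.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if alpha.shape[0] != truth.n_factors:
        raise ValueError("dirichlet_alpha length must equal K")
    rng = np.random.default_rng(seed)
    loadings = rng.dirichlet(alpha, size=n_subjects)
    dev = _deviations(loadings, truth.factor_profiles, noise_sd, rng)
    offsets = None
    if site_labels is not None and site_effect_sd > 0:
        sites = pd.Series(list(site_labels))
        per_site = {s: rng.normal(0.0, site_effect_sd, size=truth.n_edges)
                    for s in sites.unique()}
        offsets = np.stack([per_site[s] for s in sites])
    matrices = _to_matrices(dev, offsets)
    if n_timepoints is not None:
        matrices = [np.corrcoef(
            timeseries_for_matrix(m, n_timepoints, rng), rowvar=False)
            for m in matrices]
    truth.subject_loadings = loadings
    truth.site_labels = list(site_labels) if site_labels is not None else None
    return matrices, loadings


def sample_controls(n: int, parcellation: Parcellation, noise_sd: float,
                    seed: int = 0,
                    n_edges: int | None = None) -> list[np.ndarray]:
    """Reference population with zero factor signal (noise-only
    deviations, same model as :func:`sample_cohort`)."""
    if n < 2:
        raise ValueError("need at least 2 controls for reference statistics")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    e = parcellation.n_edges if n_edges is None else n_edges
    rng = np.random.default_rng(seed)
    dev = rng.normal(0.0, noise_sd, size=(n, e))
    return _to_matrices(dev)


def sample_phenotypes(loadings: np.ndarray,
                      coupling: Mapping[str, ScaleCoupling],
                      noise_sd: float, seed: int = 0,
                      site_labels: Sequence | None = None,
                      covariates: np.ndarray | None = None,
                      intercept: float = 10.0,
                      ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Item-level phenotype table linearly coupled to factor loadings.

    Coupled items are ``intercept + effect * loading_k + noise``;
    uncoupled items are intercept + pure noise.  Returns the table and a
    scale manifest (scale name -> item column names).
    """
    load = np.atleast_2d(np.asarray(loadings, dtype=float))
    n, k = load.shape
    rng = np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    manifest: dict[str, list[str]] = {}
    for scale, spec in coupling.items():
        signal = np.zeros((n, spec.n_items))
        for factor, (items, effect) in spec.couplings.items():
            if not 0 <= factor < k:
                raise ValueError(
                    f"coupling references factor {factor} but K={k}")
            for j in items:
                if not 0 <= j < spec.n_items:
                    raise ValueError(f"item index {j} out of range for "
                                     f"scale '{scale}'")
                signal[:, j] += effect * load[:, factor]
        values = intercept + signal + rng.normal(0.0, noise_sd,
                                                 size=(n, spec.n_items))
        cols = [f"{scale}_item{j + 1}" for j in range(spec.n_items)]
        manifest[scale] = cols
        for c, col in enumerate(cols):
            data[col] = values[:, c]
    table = pd.DataFrame(data)
    table.insert(0, "subject_id", [f"sub-{i + 1:04d}" for i in range(n)])
    if site_labels is not None:
        table.insert(1, "site", list(site_labels))
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(n, -1)
        for j in range(cov.shape[1]):
            table[f"cov{j + 1}"] = cov[:, j]
    return table.set_index("subject_id"), manifest


def sample_longitudinal(baseline_loadings: np.ndarray, treated_factor: int,
                        mean_delta: float, symptom_coupling_delta: float,
                        noise_sd: float, seed: int = 0,
                        delta_sd: float | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Post-treatment loadings plus a coupled symptom-change vector.

    ``mean_delta`` is the expected *decrease* of the treated factor's
    loading (positive values lower it).  Per-subject decreases are
    Normal(mean_delta, delta_sd); the treated loading is clipped at 0
    before the row is renormalized to the simplex.  The symptom change
    is ``symptom_coupling_delta * realized loading change + noise``.
    """
    base = np.atleast_2d(np.asarray(baseline_loadings, dtype=float))
    n, k = base.shape
    if not 0 <= treated_factor < k:
        raise ValueError("treated_factor out of range")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if delta_sd is None:
        delta_sd = abs(mean_delta) / 2 if mean_delta != 0 else 0.0
    rng = np.random.default_rng(seed)
    decrease = (rng.normal(mean_delta, delta_sd, size=n)
                if delta_sd > 0 else np.full(n, float(mean_delta)))
    post = base.copy()
    post[:, treated_factor] = np.clip(post[:, treated_factor] - decrease, 0.0,
                                      None)
    post = post / post.sum(axis=1, keepdims=True)
    realized = post[:, treated_factor] - base[:, treated_factor]
    delta_symptom = (symptom_coupling_delta * realized
                     + rng.normal(0.0, noise_sd, size=n))
    return post, delta_symptom


def write_cohort(out_dir: str | Path, matrices: Sequence[np.ndarray],
                 subject_ids: Sequence[str], groups: Sequence[str],
                 parcellation: Parcellation,
                 phenotypes: pd.DataFrame | None = None,
                 scales: Mapping[str, Sequence[str]] | None = None,
                 truth: GroundTruth | None = None,
                 site_labels: Sequence | None = None,
                 covariates: np.ndarray | None = None) -> Path:
    """Write a cohort to the standard file surface: one R x R CSV per
    subject, a manifest CSV, phenotype CSV + scale manifest, the
    parcellation TSV and (optionally) the ground-truth archive."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    for sid, m in zip(subject_ids, matrices):
        np.savetxt(out / "matrices" / f"{sid}.csv", m, delimiter=",",
                   fmt="%.8g")
    manifest = pd.DataFrame({"subject_id": list(subject_ids),
                             "group": list(groups)})
    if site_labels is not None:
        manifest["site"] = list(site_labels)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(len(manifest), -1)
        for j in range(cov.shape[1]):
            manifest[f"cov{j + 1}"] = cov[:, j]
    manifest.to_csv(out / "subjects.csv", index=False)
    parcellation.to_tsv(out / "parcellation.tsv")
    if phenotypes is not None:
        phenotypes.to_csv(out / "phenotypes.csv")
        if scales is not None:
            import json
            (out / "scales.json").write_text(
                json.dumps({k: list(v) for k, v in scales.items()}, indent=1))
    if truth is not None:
        gt = out / "ground_truth"
        gt.mkdir(exist_ok=True)
        np.savetxt(gt / "factor_profiles.csv", truth.factor_profiles,
                   delimiter=",", fmt="%.8g")
        if truth.subject_loadings is not None:
            np.savetxt(gt / "subject_loadings.csv", truth.subject_loadings,
                       delimiter=",", fmt="%.10g")
    return out
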