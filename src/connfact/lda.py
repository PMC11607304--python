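"""Mixed-membership factor model over signed edge-count documents.

A from-scratch batch variational Bayes implementation of latent
Dirichlet allocation.  Subjects are documents, signed connectivity
deviations are words; the fitted row-stochastic ``beta`` gives
Pr(word | factor) and the per-subject simplex loadings give
Pr(factor | subject).

The variational family is the standard mean-field one: a Dirichlet
``gamma_d`` over each document's factor proportions, a Dirichlet
``lambda_k`` over each factor's word distribution, and implicit
multinomial token responsibilities that are always kept at their
optimum, so they never need to be stored (their entropy folds into a
log-sum-exp term of the bound).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln
from scipy.stats import norm

from .connectome import CountDocument
from .association import fdr_adjust

_EPS = 1e-100

__all__ = [
    "FactorModel", "FactorProfileCI", "fit_lda", "infer_expression",
    "match_factors", "bootstrap_profiles", "threshold_profile", "elbo",
    "scan_k",
]


def _dirichlet_expectation(x: np.ndarray) -> np.ndarray:
    """E[log p] for Dirichlet rows (or a single Dirichlet vector)."""
    if x.ndim == 1:
        return digamma(x) - digamma(x.sum())
    return digamma(x) - digamma(x.sum(axis=1, keepdims=True))


def _as_count_matrix(docs: Sequence[CountDocument] | np.ndarray) -> np.ndarray:
    if isinstance(docs, np.ndarray):
        x = np.asarray(docs, dtype=float)
    else:
        x = np.asarray([d.counts for d in docs], dtype=float)
    if x.ndim != 2:
        raise ValueError("corpus must be a list of documents or an N x V array")
    if x.shape[0] == 0:
        raise ValueError("empty corpus")
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every document must contain at least one token")
    return x


@dataclass
class FactorModel:
    """Fitted LDA parameters.

    Attributes
    ----------
    beta : (K, V) array
        Row-stochastic Pr(word | factor), the posterior-mean word
        distributions.
    lambda_ : (K, V) array
        Variational Dirichlet parameters over the word distributions
        (``beta`` is ``lambda_`` normalized by row).
    alpha : (K,) array
        Dirichlet hyperparameter on factor proportions.
    eta : float
        Symmetric Dirichlet smoothing on word distributions.
    fit_log : list of float
        Per-iteration ELBO of the winning restart (non-decreasing).
    restart_elbos : list of float
        Final ELBO of each restart.
    converged : bool
        False when the winning restart hit ``max_iter`` first.
    """

    beta: np.ndarray
    lambda_: np.ndarray
    alpha: np.ndarray
    eta: float
    fit_log: list = field(default_factory=list)
    restart_elbos: list = field(default_factory=list)
    converged: bool = True
    vocabulary: list | None = None

    @property
    def n_factors(self) -> int:
        return self.beta.shape[0]

    @property
    def n_words(self) -> int:
        return self.beta.shape[1]

    def signed_profiles(self, normalize: bool = False) -> np.ndarray:
        """Per-factor signed edge profile: beta mass on ``edge+`` minus
        mass on ``edge-`` (length E = V/2).  With ``normalize`` each row
        is divided by its max |value| (display convention)."""
        e = self.n_words // 2
        prof = self.beta[:, :e] - self.beta[:, e:]
        if normalize:
            m = np.abs(prof).max(axis=1, keepdims=True)
            prof = prof / np.where(m > 0, m, 1.0)
        return prof

    def vocabulary_hash(self) -> str:
        vocab = self.vocabulary or [f"w{i}" for i in range(self.n_words)]
        return hashlib.sha256("\n".join(vocab).encode()).hexdigest()[:16]

    # -- serialization (text-only archive: meta.json + beta/lambda CSV) --

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "n_factors": int(self.n_factors),
            "n_words": int(self.n_words),
            "alpha": [float(a) for a in self.alpha],
            "eta": float(self.eta),
            "fit_log": [float(v) for v in self.fit_log],
            "restart_elbos": [float(v) for v in self.restart_elbos],
            "converged": bool(self.converged),
            "vocabulary_hash": self.vocabulary_hash(),
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))
        np.savetxt(d / "beta.csv", self.beta, delimiter=",")
        np.savetxt(d / "lambda.csv", self.lambda_, delimiter=",")
        if self.vocabulary is not None:
            (d / "vocabulary.txt").write_text("\n".join(self.vocabulary))

    @classmethod
    def load(cls, directory: str | Path,
             expect_vocabulary: Sequence[str] | None = None) -> "FactorModel":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        if meta.get("format_version") != 1:
            raise ValueError("unsupported model archive version")
        beta = np.loadtxt(d / "beta.csv", delimiter=",", ndmin=2)
        lam = np.loadtxt(d / "lambda.csv", delimiter=",", ndmin=2)
        vocab = None
        if (d / "vocabulary.txt").exists():
            vocab = (d / "vocabulary.txt").read_text().splitlines()
        model = cls(beta=beta, lambda_=lam, alpha=np.asarray(meta["alpha"]),
                    eta=float(meta["eta"]), fit_log=meta["fit_log"],
                    restart_elbos=meta["restart_elbos"],
                    converged=meta["converged"], vocabulary=vocab)
        if expect_vocabulary is not None:
            want = hashlib.sha256("\n".join(expect_vocabulary).encode()).hexdigest()[:16]
            if want != meta["vocabulary_hash"]:
                raise ValueError("model vocabulary does not match supplied data")
        return model


def _resolve_alpha(alpha: float | Sequence[float] | None, k: int) -> np.ndarray:
    if alpha is None:
        alpha = 50.0 / k
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    if a.shape == (1,):
        a = np.full(k, a[0])
    if a.shape != (k,) or np.any(a <= 0):
        raise ValueError("alpha must be a positive scalar or length-K vector")
    return a


def _e_step(x: np.ndarray, exp_elog_beta: np.ndarray, alpha: np.ndarray,
            gamma: np.ndarray | None = None, max_iter: int = 200,
            tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimize per-document gammas for fixed word distributions.

    Returns (gamma, sufficient statistics for the M-step, the token
    log-sum-exp term of the bound).  ``exp_elog_beta`` may be either
    exp(E[log beta]) during fitting or plain beta at prediction time.
    """
    n, k = x.shape[0], exp_elog_beta.shape[0]
    if gamma is None:
        gamma = np.repeat(alpha[None, :], n, axis=0) + x.sum(axis=1, keepdims=True) / k
    exp_elog_theta = np.exp(_dirichlet_expectation(gamma))
    for _ in range(max_iter):
        last = gamma
        # phi_dvk ∝ exp_elog_theta_dk * exp_elog_beta_kv, marginalized analytically
        norm = exp_elog_theta @ exp_elog_beta + _EPS
        gamma = alpha[None, :] + exp_elog_theta * ((x / norm) @ exp_elog_beta.T)
        exp_elog_theta = np.exp(_dirichlet_expectation(gamma))
        if np.mean(np.abs(gamma - last)) < tol * np.mean(gamma):
            break
    norm = exp_elog_theta @ exp_elog_beta + _EPS
    sstats = exp_elog_beta * ((x / norm).T @ exp_elog_theta).T
    ll_token = float(np.sum(x * np.log(norm)))
    return gamma, sstats, ll_token


def _theta_terms(gamma: np.ndarray, alpha: np.ndarray) -> float:
    elog = _dirichlet_expectation(gamma)
    n = gamma.shape[0]
    term = float(np.sum((alpha[None, :] - gamma) * elog))
    term += float(np.sum(gammaln(gamma)) - np.sum(gammaln(gamma.sum(axis=1))))
    term -= n * float(np.sum(gammaln(alpha)) - gammaln(alpha.sum()))
    return term


def _beta_terms(lam: np.ndarray, eta: float) -> float:
    k, v = lam.shape
    elog = _dirichlet_expectation(lam)
    term = float(np.sum((eta - lam) * elog))
    term += float(np.sum(gammaln(lam)) - np.sum(gammaln(lam.sum(axis=1))))
    term -= k * float(v * gammaln(eta) - gammaln(v * eta))
    return term


def fit_lda(docs: Sequence[CountDocument] | np.ndarray, K: int,
            alpha: float | Sequence[float] | None = None, eta: float = 0.01,
            n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-5,
            seed: int = 0,
            vocabulary: Sequence[str] | None = None,
            ) -> tuple[FactorModel, np.ndarray]:
    """Fit the factor model by batch variational EM.

    Parameters
    ----------
    docs : list of CountDocument or (N, V) count array
    K : int
        Number of factors, >= 1 (1 is the degenerate single-factor
        model, useful as an oracle).
    alpha, eta
        Dirichlet hyperparameters; ``alpha`` defaults to the symmetric
        50/K.
    n_restarts : int
        Independent random initializations; the restart with the best
        final ELBO wins (lowest restart index on ties).
    tol : float
        Relative ELBO change declaring convergence.

    Returns
    -------
    (FactorModel, loadings)
        ``loadings`` is the (N, K) array of normalized variational
        Dirichlet means, each row on the simplex.
    """
    x = _as_count_matrix(docs)
    n, v = x.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of documents ({n})")
    if eta <= 0:
        raise ValueError("eta must be positive")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    a = _resolve_alpha(alpha, K)

    best = None
    restart_elbos: list[float] = []
    root = np.random.SeedSequence(seed)
    for r, child in enumerate(root.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        lam = rng.gamma(100.0, 0.01, size=(K, v))
        exp_elog_beta = np.exp(_dirichlet_expectation(lam))
        log: list[float] = []
        gamma = None
        converged = False
        for _ in range(max_iter):
            gamma, sstats, ll_token = _e_step(x, exp_elog_beta, a, gamma=None)
            bound = ll_token + _theta_terms(gamma, a) + _beta_terms(lam, eta)
            log.append(bound)
            lam = eta + sstats
            exp_elog_beta = np.exp(_dirichlet_expectation(lam))
            if len(log) > 1 and abs(log[-1] - log[-2]) < tol * abs(log[-2]):
                converged = True
                break
        # final E-step against the last M-step so the reported bound,
        # gammas and lambda are mutually consistent
        gamma, sstats, ll_token = _e_step(x, exp_elog_beta, a, gamma=None)
        final = ll_token + _theta_terms(gamma, a) + _beta_terms(lam, eta)
        log.append(final)
        restart_elbos.append(final)
        if best is None or final > best[0] + 1e-12:
            best = (final, lam, gamma, log, converged)

    final, lam, gamma, log, converged = best
    if not converged:
        warnings.warn("LDA did not converge within max_iter", RuntimeWarning)
    beta = lam / lam.sum(axis=1, keepdims=True)
    loadings = gamma / gamma.sum(axis=1, keepdims=True)
    model = FactorModel(beta=beta, lambda_=lam, alpha=a, eta=float(eta),
                        fit_log=log, restart_elbos=restart_elbos,
                        converged=converged,
                        vocabulary=list(vocabulary) if vocabulary else None)
    return model, loadings


def infer_expression(model: FactorModel,
                     doc: CountDocument | np.ndarray,
                     max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Predict factor expression for an unseen subject with ``beta``
    held fixed (per-document variational inference only).

    Deterministic: gammas start from uniform responsibilities.
    Accepts a single document or an (N, V) batch; returns a simplex
    vector or an (N, K) array accordingly.
    """
    single = isinstance(doc, CountDocument) or np.asarray(doc).ndim == 1
    if isinstance(doc, CountDocument):
        x = doc.counts[None, :].astype(float)
    else:
        x = np.atleast_2d(np.asarray(doc, dtype=float))
    if x.shape[1] != model.n_words:
        raise ValueError(
            f"document vocabulary size {x.shape[1]} does not match model "
            f"({model.n_words})")
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("cannot infer expression for an empty document")
    gamma, _, _ = _e_step(x, model.beta, model.alpha,
                          max_iter=max_iter, tol=tol)
    loadings = gamma / gamma.sum(axis=1, keepdims=True)
    return loadings[0] if single else loadings


def match_factors(beta_a: np.ndarray, beta_b: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` maximizing total Pearson correlation between
    ``beta_a[i]`` and ``beta_b[perm[i]]``, solved exactly by optimal
    assignment.  Ties resolve to the lexicographically smallest
    permutation."""
    a = np.atleast_2d(np.asarray(beta_a, dtype=float))
    b = np.atleast_2d(np.asarray(beta_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("profile matrices must have identical shape")
    k = a.shape[0]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    denom = np.outer(an, bn)
    corr = np.where(denom > 0, (ac @ bc.T) / np.where(denom > 0, denom, 1.0), 0.0)
    # tiny index-based tiebreak keeps ties at identity-leaning assignments
    tie = -1e-12 * np.abs(np.arange(k)[:, None] - np.arange(k)[None, :])
    rows, cols = linear_sum_assignment(-(corr + tie))
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return perm


@dataclass(frozen=True)
class FactorProfileCI:
    """Bootstrap summary of per-factor signed edge profiles.

    All arrays are (K, E).  ``mask`` is True where the BH-adjusted
    two-sided normal p of the bootstrap z-score is below the alpha used
    at construction.
    """

    signed_profile: np.ndarray
    boot_mean: np.ndarray
    boot_sd: np.ndarray
    z: np.ndarray
    q: np.ndarray
    mask: np.ndarray
    alpha: float
    n_boot: int


def bootstrap_profiles(docs: Sequence[CountDocument] | np.ndarray, K: int,
                       B: int = 100, alpha_level: float = 0.05,
                       seed: int = 0, **fit_kwargs) -> FactorProfileCI:
    """Edge-wise significance of factor profiles by subject bootstrap.

    Fits the full corpus once, then refits ``B`` resamples (subjects
    drawn with replacement), matching each replicate's factors back to
    the full-data fit.  Per edge, z = bootstrap mean / bootstrap sd of
    the signed profile, two-sided normal p, Benjamini-Hochberg across
    all K*E tests.
    """
    if B < 20:
        raise ValueError("B must be >= 20 for a stable bootstrap sd")
    x = _as_count_matrix(docs)
    n = x.shape[0]
    fit_kwargs.setdefault("n_restarts", 3)
    model, _ = fit_lda(x, K, seed=seed, **fit_kwargs)
    full_signed = model.signed_profiles()

    boot_kwargs = dict(fit_kwargs)
    boot_kwargs["n_restarts"] = 1
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(1,)))
    reps = np.empty((B, K, model.n_words // 2))
    for b in range(B):
        take = rng.integers(0, n, size=n)
        m_b, _ = fit_lda(x[take], K, seed=seed + 1000 + b, **boot_kwargs)
        perm = match_factors(model.beta, m_b.beta)
        reps[b] = m_b.signed_profiles()[perm]

    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0),
                     np.where(mean != 0, np.inf * np.sign(mean), 0.0))
    p = np.where(np.isinf(z), 0.0, 2.0 * norm.sf(np.abs(np.nan_to_num(z))))
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    q = fdr_adjust(p.ravel()).reshape(p.shape)
    mask = q < alpha_level
    return FactorProfileCI(signed_profile=full_signed, boot_mean=mean,
                           boot_sd=sd, z=z, q=q, mask=mask,
                           alpha=alpha_level, n_boot=B)


def threshold_profile(profile: np.ndarray, fraction: float = 0.5,
                      significance_mask: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask retaining the ``ceil(fraction * n_candidate)`` edges
    of largest |weight| among candidate edges (nonzero weight,
    intersected with ``significance_mask`` when given).  Ties broken by
    edge index."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    w = np.asarray(profile, dtype=float)
    cand = w != 0
    if significance_mask is not None:
        cand &= np.asarray(significance_mask, dtype=bool)
    idx = np.flatnonzero(cand)
    keep = np.zeros(w.shape[0], dtype=bool)
    if idx.size == 0:
        return keep
    m = int(np.ceil(fraction * idx.size))
    order = idx[np.lexsort((idx, -np.abs(w[idx])))]
    keep[order[:m]] = True
    return keep


def elbo(model: FactorModel, docs: Sequence[CountDocument] | np.ndarray,
         max_iter: int = 500) -> float:
    """Evidence lower bound of the fitted variational posterior on a
    corpus (document gammas re-optimized, word posteriors fixed).

    Includes the word-distribution prior/entropy terms, so the value is
    a certified lower bound on the exact log-evidence with ``beta``
    integrated out.
    """
    x = _as_count_matrix(docs)
    exp_elog_beta = np.exp(_dirichlet_expectation(model.lambda_))
    gamma, _, ll_token = _e_step(x, exp_elog_beta, model.alpha,
                                 max_iter=max_iter, tol=1e-10)
    return ll_token + _theta_terms(gamma, model.alpha) + _beta_terms(
        model.lambda_, model.eta)


def predictive_log_likelihood(model: FactorModel,
                              docs: Sequence[CountDocument] | np.ndarray) -> float:
    """Plug-in held-out log-likelihood: sum_dv n_dv log(theta_d . beta_v)
    with theta from :func:`infer_expression`."""
    x = _as_count_matrix(docs)
    theta = infer_expression(model, x)
    probs = theta @ model.beta + _EPS
    return float(np.sum(x * np.log(probs)))


def scan_k(docs: Sequence[CountDocument] | np.ndarray,
           K_range: Iterable[int], n_folds: int = 5, seed: int = 0,
           **fit_kwargs) -> "pd.DataFrame":
    """Cross-validated held-out predictive log-likelihood per K.

    Documents are split into ``n_folds`` folds; for each K the model is
    fit on the training folds and scored on the held-out fold via
    per-token predictive log-likelihood.  Returns a table; no automatic
    selection is made.
    """
    import pandas as pd

    x = _as_count_matrix(docs)
    n = x.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ValueError("n_folds must be in [2, n_docs]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    rows = []
    for k in K_range:
        total_ll = 0.0
        total_tokens = 0.0
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            model, _ = fit_lda(x[train_idx], k, seed=seed + 31 * f, **fit_kwargs)
            total_ll += predictive_log_likelihood(model, x[test_idx])
            total_tokens += x[test_idx].sum()
        rows.append({"K": int(k), "heldout_loglik": total_ll,
                     "per_token": total_ll / total_tokens})
    return pd.DataFrame(rows)


def brute_force_match(beta_a: np.ndarray, beta_b: np.ndarray) -> np.ndarray:
    """Reference implementation of :func:`match_factors` by exhaustive
    enumeration over all K! permutations (test oracle; K <= ~8)."""
    a = np.atleast_2d(np.asarray(beta_a, dtype=float))
    b = np.atleast_2d(np.asarray(beta_b, dtype=float))
    k = a.shape[0]
    best_perm, best_score = None, -np.inf
    for perm in permutations(range(k)):
        score = sum(float(np.corrcoef(a[i], b[perm[i]])[0, 1])
                    for i in range(k))
        if score > best_score + 1e-12:
            best_perm, best_score = perm, score
    return np.asarray(best_perm)
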