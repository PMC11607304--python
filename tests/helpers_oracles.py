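"""Independent oracles used by the test suite.

Everything here is deliberately brute-force / closed-form and shares no
code with the implementation under test.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import gammaln


def exact_log_evidence(X, alpha, eta) -> float:
    """Exact LDA log-evidence by exhaustive enumeration of all topic
    assignments (Dirichlet-multinomial closed forms for the theta and
    beta integrals).  Exponential in the total token count."""
    X = np.asarray(X, dtype=int)
    n_docs, n_words = X.shape
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.shape[0]
    tokens = [np.repeat(np.arange(n_words), row) for row in X]
    n_tok = [t.size for t in tokens]
    total = int(sum(n_tok))
    if total > 14:
        raise ValueError("enumeration oracle limited to <= 14 tokens")
    logps = []
    for z_all in product(range(k), repeat=total):
        z_all = np.asarray(z_all)
        offset, lp = 0, 0.0
        ckv = np.zeros((k, n_words))
        for d in range(n_docs):
            z = z_all[offset:offset + n_tok[d]]
            offset += n_tok[d]
            mdk = np.bincount(z, minlength=k)
            lp += (gammaln(alpha.sum()) - gammaln(alpha.sum() + n_tok[d])
                   + np.sum(gammaln(alpha + mdk) - gammaln(alpha)))
            np.add.at(ckv, (z, tokens[d]), 1.0)
        for t in range(k):
            nk = ckv[t].sum()
            lp += (gammaln(n_words * eta) - gammaln(n_words * eta + nk)
                   + np.sum(gammaln(eta + ckv[t]) - gammaln(eta)))
        logps.append(lp)
    logps = np.asarray(logps)
    m = logps.max()
    return float(m + np.log(np.exp(logps - m).sum()))


def bh_by_hand(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up from the textbook definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.corrcoef(a, b)[0, 1])
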