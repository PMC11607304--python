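"""Individual-level overlap between a subject's strongest edges and a
factor's significant connectivity profile (Dice coefficient), plus
region-level contribution ranking."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .association import fdr_adjust
from .connectome import edge_index
from .lda import FactorProfileCI
from .parcellation import Parcellation

__all__ = [
    "EdgeSet", "DiceResult", "top_fraction_edges", "paired_altered_edges",
    "factor_profile_set", "dice", "top_contributing_regions",
]


@dataclass(frozen=True)
class EdgeSet:
    """A set of edge indices into the shared half-vectorization order.

    ``provenance`` records how the set was derived
    (``top-fraction`` | ``paired-altered`` | ``factor-profile``).
    """

    indices: frozenset
    n_edges_total: int
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        idx = np.fromiter(self.indices, dtype=int, count=len(self.indices))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_edges_total):
            raise ValueError("edge indices out of range")

    def __len__(self) -> int:
        return len(self.indices)

    def as_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_edges_total, dtype=bool)
        mask[list(self.indices)] = True
        return mask


@dataclass(frozen=True)
class DiceResult:
    coefficient: float
    size_a: int
    size_b: int
    size_intersection: int

    @property
    def percent(self) -> float:
        return 100.0 * self.coefficient


def top_fraction_edges(values: np.ndarray, fraction: float = 0.10,
                       signed: bool = True) -> EdgeSet:
    """The ``ceil(fraction * E)`` edges of largest connection strength.

    ``signed=True`` ranks by |value| so hyper- and hypo-connectivity
    both count; ``signed=False`` ranks by raw value.  Ties at the cutoff
    are broken by edge index (lowest wins).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    v = np.asarray(values, dtype=float)
    e = v.shape[0]
    key = np.abs(v) if signed else v
    m = int(np.ceil(fraction * e))
    order = np.lexsort((np.arange(e), -key))
    return EdgeSet(frozenset(order[:m].tolist()), e, provenance="top-fraction")


def paired_altered_edges(pre: np.ndarray, post: np.ndarray,
                         alpha: float = 0.05) -> EdgeSet:
    """Edges significantly altered between paired pre/post edge
    vectors: per-edge paired t-test on (post - pre), BH-FDR across all
    edges, retained at q < alpha."""
    a = np.atleast_2d(np.asarray(pre, dtype=float))
    b = np.atleast_2d(np.asarray(post, dtype=float))
    if a.shape != b.shape:
        raise ValueError("pre and post must have the same shape")
    n, e = a.shape
    if n < 3:
        raise ValueError("need at least 3 paired subjects")
    d = b - a
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (np.where(sd > 0, sd, 1.0) / np.sqrt(n)),
                     np.where(mean != 0, np.inf * np.sign(mean), 0.0))
    from scipy.stats import t as t_dist
    p = np.where(np.isinf(t), 0.0,
                 2.0 * t_dist.sf(np.abs(np.nan_to_num(t)), df=n - 1))
    p = np.where((sd == 0) & (mean == 0), 1.0, p)
    q = fdr_adjust(p)
    return EdgeSet(frozenset(np.flatnonzero(q < alpha).tolist()), e,
                   provenance="paired-altered")


def factor_profile_set(ci: FactorProfileCI, factor: int) -> EdgeSet:
    """Significant-profile edge set of one factor from the bootstrap
    significance mask."""
    mask = np.asarray(ci.mask[factor], dtype=bool)
    return EdgeSet(frozenset(np.flatnonzero(mask).tolist()), mask.shape[0],
                   provenance="factor-profile")


def dice(a: EdgeSet, b: EdgeSet) -> DiceResult:
    """Dice coefficient 2|A∩B| / (|A| + |B|).

    Raises
    ------
    ValueError
        If either operand is empty (the coefficient is undefined, not
        zero).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Dice coefficient is undefined for an empty edge set")
    inter = len(a.indices & b.indices)
    coef = 2.0 * inter / (len(a) + len(b))
    return DiceResult(coefficient=coef, size_a=len(a), size_b=len(b),
                      size_intersection=inter)


def top_contributing_regions(edge_set: EdgeSet, parcellation: Parcellation,
                             weights: np.ndarray | None = None) -> pd.DataFrame:
    """Rank regions by incident-edge count (or |weight| sum) within an
    edge set.  Descending score; ties broken by region order."""
    idx = edge_index(parcellation.n_regions)
    sel = sorted(edge_set.indices)
    score = np.zeros(parcellation.n_regions)
    if weights is None:
        w = np.ones(len(sel))
    else:
        w = np.abs(np.asarray(weights, dtype=float))[sel]
    for e_i, wv in zip(sel, w):
        i, j = idx[e_i]
        score[i] += wv
        score[j] += wv
    order = np.lexsort((np.arange(score.size), -score))
    return pd.DataFrame({
        "region_id": [parcellation.region_ids[i] for i in order],
        "network": [parcellation.network_of[parcellation.region_ids[i]]
                    for i in order],
        "score": score[order],
        "rank": np.arange(1, score.size + 1),
    })
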