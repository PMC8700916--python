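"""Minimum-redundancy-maximum-relevance feature ranking on categorical codes.

Relevance of a feature is its plug-in mutual information with the class
label; redundancy is its mean mutual information with the features already
selected.  The ranking is built incrementally: the first entry maximises
relevance, and entry m maximises

    I(x_j; c) - (1 / (m - 1)) * sum over selected x' of I(x_j; x')

over the not-yet-selected features.  Ranking stops at a cap (500 by
default).  Mutual information is the maximum-likelihood plug-in estimate in
bits (log base 2); the base only rescales scores and never changes the
ranking.  Ties are broken by higher relevance, then by column order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FeatureRef

DEFAULT_CAP = 500


@dataclass
class RankedFeature:
    ref: FeatureRef
    selection_score: float
    relevance: float


@dataclass
class RankedFeatureList:
    """mRMR-ordered features, most informative first."""

    entries: list[RankedFeature]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    def refs(self) -> list[FeatureRef]:
        return [e.ref for e in self.entries]

    def head(self, n: int) -> "RankedFeatureList":
        return RankedFeatureList(self.entries[:n])


def _as_codes(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError("expected a 1-D categorical vector")
    _, codes = np.unique(x, return_inverse=True)
    return codes


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two categorical vectors, in bits.

    Empty contingency cells contribute zero (0*log 0 = 0); no pseudo-counts.
    Symmetric, non-negative, and invariant under relabelling of categories.
    """
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    cx = _as_codes(x)
    cy = _as_codes(y)
    n = cx.size
    kx, ky = cx.max() + 1, cy.max() + 1
    joint = np.bincount(cx * ky + cy, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (px[:, None] * py[None, :]))
    return float(np.nansum(terms))


def _mi_vector(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mutual information of every column of X with the vector y, in bits.

    Vectorised over columns; X entries must be small integers (any offset).
    """
    X = np.asarray(X)
    n, p = X.shape
    Xs = (X - X.min()).astype(np.int64)
    cy = _as_codes(np.asarray(y))
    ky = cy.max() + 1
    kx = int(Xs.max()) + 1
    mi = np.zeros(p)
    # p(a) per column, p(b) global, joint via masked column counts
    pa = np.stack([(Xs == a).mean(axis=0) for a in range(kx)])  # (kx, p)
    pb = np.bincount(cy, minlength=ky) / n
    for b in range(ky):
        rows = cy == b
        Xb = Xs[rows]
        for a in range(kx):
            pab = (Xb == a).sum(axis=0) / n  # (p,)
            denom = pa[a] * pb[b]
            with np.errstate(divide="ignore", invalid="ignore"):
                term = pab * np.log2(pab / denom)
            mi += np.where(pab > 0, term, 0.0)
    return mi


def max_relevance_scores(codes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature relevance: I(feature; class) for every column, in bits."""
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    if codes.shape[0] != labels.shape[0]:
        raise ValueError("row count of codes must match label length")
    return _mi_vector(codes, labels)


def mrmr_rank(
    codes: np.ndarray,
    labels: np.ndarray,
    refs: list[FeatureRef] | None = None,
    cap: int = DEFAULT_CAP,
) -> RankedFeatureList:
    """Incremental mRMR ranking of the columns of a joined categorical matrix.

    Parameters
    ----------
    codes
        (n_samples, n_features) small-integer categorical matrix.
    labels
        length-n vector in {+1, -1} (any two-class coding works).
    refs
        FeatureRef per column; synthesised positional refs if omitted.
    cap
        Maximum list length (default 500).

    Pairwise feature-feature information is computed incrementally, only
    against already-selected features, which is exactly what the criterion
    requires and avoids the full pairwise matrix.
    """
    codes = np.asarray(codes)
    labels = np.asarray(labels)
    n, p = codes.shape
    if p < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if refs is None:
        refs = [FeatureRef("all", f"f{j}", j) for j in range(p)]
    if len(refs) != p:
        raise ValueError("refs length must match feature count")

    relevance = _mi_vector(codes, labels)
    k = min(cap, p)
    selected: list[RankedFeature] = []
    remaining = np.ones(p, dtype=bool)
    redundancy_sum = np.zeros(p)

    def _argmax(score: np.ndarray) -> int:
        # tie rule: max score, then max relevance, then lowest column index
        cand = np.flatnonzero(remaining)
        s = score[cand]
        best = s.max()
        tied = cand[np.isclose(s, best, rtol=0, atol=1e-12)]
        if tied.size > 1:
            r = relevance[tied]
            tied = tied[np.isclose(r, r.max(), rtol=0, atol=1e-12)]
        return int(tied[0])

    j = _argmax(relevance)
    selected.append(RankedFeature(refs[j], float(relevance[j]), float(relevance[j])))
    remaining[j] = False
    last = j
    for m in range(2, k + 1):
        redundancy_sum += _mi_vector(codes, codes[:, last])
        score = relevance - redundancy_sum / (m - 1)
        score[~remaining] = -np.inf
        j = _argmax(score)
        selected.append(RankedFeature(refs[j], float(score[j]), float(relevance[j])))
        remaining[j] = False
        last = j
    return RankedFeatureList(selected)
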