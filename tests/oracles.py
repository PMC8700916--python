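"""Independent reference implementations used only to check the package.

Deliberately naive: plain double loops, exhaustive pair counting, and a
generic nonlinear-programming solve of the SVM dual.  None of them share
code with the implementation under test.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy.optimize import minimize


def mi_oracle(x, y) -> float:
    """Plug-in mutual information in bits via explicit cell sums."""
    x, y = list(x), list(y)
    n = len(x)
    cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
    total = 0.0
    for (a, b), nab in cxy.items():
        pab = nab / n
        total += pab * math.log2(pab / ((cx[a] / n) * (cy[b] / n)))
    return total


def entropy_oracle(x) -> float:
    n = len(list(x))
    return -sum((c / n) * math.log2(c / n) for c in Counter(x).values())


def brute_force_mrmr(codes: np.ndarray, labels, cap: int) -> list[int]:
    """Step-by-step maximisation of relevance minus mean redundancy,
    re-evaluating every candidate at every step with ``mi_oracle``.

    Ties: higher criterion, then higher relevance, then lower column index.
    """
    codes = np.asarray(codes)
    p = codes.shape[1]
    relevance = [mi_oracle(codes[:, j], labels) for j in range(p)]
    order: list[int] = []
    remaining = set(range(p))
    while remaining and len(order) < cap:
        best_j, best_key = None, None
        for j in sorted(remaining):
            if order:
                red = sum(mi_oracle(codes[:, j], codes[:, s]) for s in order)
                score = relevance[j] - red / len(order)
            else:
                score = relevance[j]
            key = (round(score, 10), round(relevance[j], 10), -j)
            if best_key is None or key > best_key:
                best_j, best_key = j, key
        order.append(best_j)
        remaining.discard(best_j)
    return order


def auc_pair_count(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting; ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == -1]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def svm_dual_qp(K: np.ndarray, y: np.ndarray, C: float):
    """Solve max_a sum(alpha) - 1/2 a^T K a, a_i = alpha_i y_i,
    0 <= alpha_i <= C, sum a = 0, with a generic NLP solver (SLSQP).

    Returns (signed duals a, bias, objective).  The bias averages the KKT
    condition y_i - f0(x_i) over margin (non-bound) support vectors.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)

    def neg_obj(alpha):
        a = alpha * y
        return -(alpha.sum() - 0.5 * a @ K @ a)

    def neg_obj_grad(alpha):
        a = alpha * y
        return -(np.ones(n) - y * (K @ a))

    cons = {"type": "eq", "fun": lambda alpha: alpha @ y,
            "jac": lambda alpha: y}
    res = minimize(
        neg_obj, np.full(n, min(C, 1.0) / 2), jac=neg_obj_grad,
        bounds=[(0.0, C)] * n, constraints=[cons], method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    alpha = res.x
    a = alpha * y
    f0 = K @ a
    margin = (alpha > 1e-6 * C) & (alpha < C * (1 - 1e-6))
    if margin.any():
        b = float(np.mean(y[margin] - f0[margin]))
    else:  # all bound: bias bracketed by KKT inequalities, take midpoint
        lo = np.max((y - f0)[(y > 0) & (alpha > C - 1e-8) | (y < 0) & (alpha < 1e-8)])
        hi = np.min((y - f0)[(y < 0) & (alpha > C - 1e-8) | (y > 0) & (alpha < 1e-8)])
        b = float((lo + hi) / 2)
    return a, b, float(alpha.sum() - 0.5 * a @ K @ a)
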