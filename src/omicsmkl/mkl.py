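"""simpleMKL-style multiple kernel learning over per-block omics kernels.

The classifier is a soft-margin SVM whose kernel is a convex combination
K = sum_m d_m K_m of base kernels, with the weights d constrained to the
probability simplex (d_m >= 0, sum_m d_m = 1).  Training alternates two
steps until the duality gap closes:

1. at fixed weights, solve the standard SVM dual on the combined kernel;
2. take a reduced-gradient descent step on d within the simplex, using
   dJ/dd_m = -1/2 sum_ij a_i a_j K_m(x_i, x_j) (a_i the signed dual
   coefficients), with a line search on the objective.

The simplex constraint drives many kernel weights to exactly zero, so the
fitted model reveals which omics blocks (and kernel shapes) carry the
discriminative signal.  The decision function is
f(x) = sum_i a_i K(x, x_i) + b; its sign is the predicted class, with 0
mapped to +1.

``OmicsMKL`` wraps the full per-dataset pipeline — ternary discretization,
mRMR ranking, truncation to the top-N features, per-block standardization,
kernel construction, and simpleMKL training — in a statsmodels-style
model/results pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .dataset import FeatureRef, MultiOmicsDataset
from .discretize import DatasetDiscretizer, DiscretizationParams
from .kernels import FittedKernel, KernelMatrix, KernelSpec, combine_kernels
from .mrmr import DEFAULT_CAP, RankedFeatureList, mrmr_rank

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SVM dual at fixed kernel weights
# ---------------------------------------------------------------------------


@dataclass
class SVMSolution:
    """Dual solution: signed coefficients a_i = alpha_i * y_i (zero off the
    support set), bias, and the dual objective
    sum_i alpha_i - 1/2 sum_ij a_i a_j K_ij."""

    signed_dual: np.ndarray
    bias: float
    objective: float

    @property
    def alpha(self) -> np.ndarray:
        return np.abs(self.signed_dual)

    @property
    def support_(self) -> np.ndarray:
        return np.flatnonzero(self.signed_dual != 0)


try:  # low-overhead path for the many small solves inside simpleMKL
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None


def solve_svm_fixed_weights(
    K: np.ndarray | KernelMatrix,
    labels: np.ndarray,
    C: float = 1.0,
    svm_tol: float = 1e-8,
    class_weight: dict | None = None,
) -> SVMSolution:
    """Solve the soft-margin SVM dual on a precomputed kernel.

    Returns coefficients satisfying 0 <= alpha_i <= C and
    sum_i alpha_i y_i = 0, with the bias recovered from the KKT conditions.
    """
    Kv = K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if set(classes) != {-1, 1}:
        raise ValueError("labels must be coded +1 / -1")
    a = np.zeros(len(y))
    if _libsvm is not None and class_weight is None:
        support, _, _, coef, intercept = _libsvm.fit(
            np.ascontiguousarray(Kv, dtype=np.float64),
            y.astype(np.float64),
            svm_type=0,
            kernel="precomputed",
            C=C,
            tol=svm_tol,
        )[:5]
        a[support] = coef[0]
        b = float(intercept[0])
        # libsvm orients the pair by first-seen label; the box constraint
        # alpha_i = a_i * y_i >= 0 identifies the orientation unambiguously
        if (a * y).sum() < 0:
            a, b = -a, -b
    else:
        svc = SVC(C=C, kernel="precomputed", tol=svm_tol, class_weight=class_weight)
        svc.fit(Kv, y)
        a[svc.support_] = svc.dual_coef_[0]
        b = float(svc.intercept_[0])
    alpha = a * y
    obj = float(alpha.sum() - 0.5 * a @ Kv @ a)
    return SVMSolution(signed_dual=a, bias=b, objective=obj)


# ---------------------------------------------------------------------------
# simpleMKL reduced-gradient loop
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceRecord:
    n_iter: int
    converged: bool
    final_gap: float
    objective_history: list[float] = field(default_factory=list)
    gap_history: list[float] = field(default_factory=list)
    weight_history: list[np.ndarray] = field(default_factory=list)
    warning: str | None = None


@dataclass
class MKLFit:
    """Raw simpleMKL output: simplex weights, dual solution, diagnostics."""

    kernel_weights: np.ndarray
    signed_dual: np.ndarray
    bias: float
    objective: float
    convergence: ConvergenceRecord


def _quadforms(mats: list[np.ndarray], a: np.ndarray) -> np.ndarray:
    """S_m = 1/2 a^T K_m a for every base kernel (dJ/dd_m = -S_m)."""
    return np.array([0.5 * a @ Km @ a for Km in mats])


def _descent_direction(d: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """Reduced-gradient descent direction on the simplex.

    The component with the largest weight anchors the equality constraint;
    zero-weight components whose reduced gradient is positive are frozen so
    the direction stays feasible.
    """
    mu = int(np.argmax(d))
    red = grad - grad[mu]
    D = -red
    D[(d <= 1e-12) & (red > 0)] = 0.0
    D[mu] = 0.0
    D[mu] = -D.sum()
    return D


def train_simplemkl(
    kernels: list[KernelMatrix] | list[np.ndarray],
    labels: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 200,
    svm_tol: float = 1e-8,
    class_weight: dict | None = None,
) -> MKLFit:
    """Learn simplex kernel weights and SVM duals by alternating descent.

    Terminates when the relative duality gap
    (max_m S_m - sum_m d_m S_m) / |J| drops to ``tol`` or after ``max_iter``
    outer iterations (then the fit is returned with a warning recorded).
    The objective is non-increasing across accepted line-search steps.
    """
    mats = [k.values if isinstance(k, KernelMatrix) else np.asarray(k, float) for k in kernels]
    M = len(mats)
    if M == 0:
        raise ValueError("at least one kernel is required")
    y = np.asarray(labels, dtype=int)

    def _solve(d: np.ndarray) -> SVMSolution:
        return solve_svm_fixed_weights(
            combine_kernels(mats, d), y, C=C, svm_tol=svm_tol, class_weight=class_weight
        )

    d = np.full(M, 1.0 / M)
    sol = _solve(d)
    J = sol.objective
    rec = ConvergenceRecord(0, False, np.inf)
    rec.objective_history.append(J)
    rec.weight_history.append(d.copy())

    def _line_search(d, D, J, gamma_max):
        """Best improving step along D in (0, gamma_max]: golden section plus
        a geometric backtracking sweep.  Returns (gamma, J_new, sol) or None."""
        cache: dict[float, tuple[float, SVMSolution]] = {}

        def _eval(g: float) -> float:
            if g not in cache:
                dd = np.clip(d + g * D, 0.0, None)
                dd /= dd.sum()
                s = _solve(dd)
                cache[g] = (s.objective, s)
            return cache[g][0]

        invphi = (np.sqrt(5.0) - 1) / 2
        lo, hi = 0.0, gamma_max
        _eval(gamma_max)
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1, f2 = _eval(x1), _eval(x2)
        for _ in range(4):
            if f1 <= f2:
                hi, x2, f2 = x2, x1, f1
                x1 = hi - invphi * (hi - lo)
                f1 = _eval(x1)
            else:
                lo, x1, f1 = x1, x2, f2
                x2 = lo + invphi * (hi - lo)
                f2 = _eval(x2)
        if min(J_ for J_, _ in cache.values()) >= J - 1e-12:
            for k in range(1, 14):  # backtracking sweep near gamma = 0
                if _eval(gamma_max * 0.5**k) < J - 1e-12:
                    break
        g_best = min(cache, key=lambda g: cache[g][0])
        J_best, sol_best = cache[g_best]
        if J_best >= J - 1e-12:
            return None
        return g_best, J_best, sol_best

    for it in range(1, max_iter + 1):
        S = _quadforms(mats, sol.signed_dual)
        gap = float((S.max() - d @ S) / max(abs(J), 1e-12))
        rec.gap_history.append(gap)
        if gap <= tol:
            rec.n_iter, rec.converged, rec.final_gap = it - 1, True, gap
            break
        grad = -S
        D = _descent_direction(d, grad)
        step = None
        if np.max(np.abs(D)) > 1e-12:
            neg = D < -1e-15
            gamma_max = float(np.min(d[neg] / -D[neg])) if neg.any() else 1.0
            step = _line_search(d, D, J, gamma_max)
        if step is None:
            # conditional-gradient fallback: moving toward the kernel with
            # the largest quadratic form is a descent direction whenever the
            # duality gap is positive
            D = -d.copy()
            D[int(np.argmax(S))] += 1.0
            step = _line_search(d, D, J, 1.0)
        if step is None:
            rec.n_iter, rec.converged, rec.final_gap = it - 1, gap <= tol, gap
            rec.warning = "no descent step found before the gap closed"
            break
        best_gamma, best_J, best_sol = step
        d = np.clip(d + best_gamma * D, 0.0, None)
        d /= d.sum()
        sol, J = best_sol, best_J
        rec.objective_history.append(J)
        rec.weight_history.append(d.copy())
    else:
        S = _quadforms(mats, sol.signed_dual)
        gap = float((S.max() - d @ S) / max(abs(J), 1e-12))
        rec.gap_history.append(gap)
        rec.n_iter, rec.converged, rec.final_gap = max_iter, gap <= tol, gap
        if not rec.converged:
            rec.warning = f"max_iter={max_iter} reached with gap {gap:.3g}"
            logger.warning("simpleMKL: %s", rec.warning)

    if rec.final_gap is np.inf:  # loop broke before setting (defensive)
        rec.final_gap = rec.gap_history[-1] if rec.gap_history else np.inf
    return MKLFit(
        kernel_weights=d,
        signed_dual=sol.signed_dual,
        bias=sol.bias,
        objective=J,
        convergence=rec,
    )


# ---------------------------------------------------------------------------
# Model / Results pair over a MultiOmicsDataset
# ---------------------------------------------------------------------------


class OmicsMKL:
    """Multi-omics MKL classifier with mRMR filter-wrapper feature selection.

    Built from a :class:`MultiOmicsDataset`; ``fit`` runs the full training
    pipeline on that dataset and returns an :class:`OmicsMKLResults`.

    Parameters
    ----------
    dataset
        Training data (labels in {+1, -1}).
    n_features
        How many top-ranked features to keep (the wrapper's N).  ``None``
        keeps the whole ranked list (up to ``cap``).
    alpha
        Half-width multiplier of the ternary discretization band.
    cap
        Maximum mRMR list length.
    kernel_families
        Kernel shapes built per block (default: gaussian + polynomial).
    C, tol, max_iter
        SVM cost, simpleMKL relative duality-gap threshold, and iteration
        budget.
    ranked
        Precomputed ranking (skips discretization + mRMR), e.g. when the
        wrapper evaluates many N on one ranking.
    """

    def __init__(
        self,
        dataset: MultiOmicsDataset,
        n_features: int | None = None,
        *,
        alpha: float = 0.5,
        cap: int = DEFAULT_CAP,
        kernel_families: tuple[str, ...] = ("gaussian", "polynomial"),
        degree: int = 2,
        offset: float = 1.0,
        C: float = 1.0,
        tol: float = 1e-3,
        max_iter: int = 200,
        class_weight: dict | None = None,
        ranked: RankedFeatureList | None = None,
    ) -> None:
        self.dataset = dataset
        self.n_features = n_features
        self.alpha = alpha
        self.cap = cap
        self.kernel_families = tuple(kernel_families)
        self.degree = degree
        self.offset = offset
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.class_weight = class_weight
        self.ranked = ranked

    def rank_features(self) -> RankedFeatureList:
        """Discretize (band statistics from this dataset) and mRMR-rank."""
        disc = DatasetDiscretizer(DiscretizationParams(alpha=self.alpha))
        codes = disc.fit_transform(self.dataset)
        return mrmr_rank(
            codes.values, self.dataset.labels,
            refs=self.dataset.feature_refs(), cap=self.cap,
        )

    def fit(self) -> "OmicsMKLResults":
        ds = self.dataset
        ranked = self.ranked if self.ranked is not None else self.rank_features()
        n_keep = len(ranked) if self.n_features is None else min(self.n_features, len(ranked))
        selected = ranked.head(n_keep)

        by_block: dict[str, list[FeatureRef]] = {name: [] for name in ds.block_names}
        for entry in selected:
            by_block[entry.ref.block_name].append(entry.ref)

        scalers: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
        fitted: list[FittedKernel] = []
        for block in ds.blocks:
            refs = by_block[block.name]
            if not refs:
                logger.warning(
                    "block %r: no selected features; its kernels are omitted",
                    block.name,
                )
                continue
            cols = [r.column_index for r in refs]
            X = block.values[:, cols]
            mu = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            sd = np.where(sd > 0, sd, 1.0)
            scalers[block.name] = (mu, sd, cols)
            Xs = (X - mu) / sd
            for family in self.kernel_families:
                fitted.append(
                    FittedKernel(
                        Xs,
                        KernelSpec(block.name, family, degree=self.degree, offset=self.offset),
                    )
                )
        if not fitted:
            raise ValueError("no kernels could be built: no features selected")

        fit = train_simplemkl(
            [fk.gram() for fk in fitted],
            ds.labels,
            C=self.C,
            tol=self.tol,
            max_iter=self.max_iter,
            class_weight=self.class_weight,
        )
        return OmicsMKLResults(self, selected, scalers, fitted, fit)


class OmicsMKLResults:
    """Fitted MKL classifier: kernel weights, duals, diagnostics, prediction.

    Attributes
    ----------
    kernel_weights_ : ndarray
        Simplex weights, one per base kernel (see ``kernel_specs_``).
    dual_coef_ : ndarray
        Signed dual coefficients a_i = alpha_i y_i over training samples.
    intercept_ : float
        Bias b of the decision function.
    selected_features_ : RankedFeatureList
        The retained, mRMR-ordered features.
    convergence_ : ConvergenceRecord
        Iterations, objective/gap/weight history, warning flag.
    """

    def __init__(self, model, selected, scalers, fitted_kernels, fit: MKLFit) -> None:
        self.model = model
        self.selected_features_ = selected
        self._scalers = scalers
        self._kernels = fitted_kernels
        self.kernel_specs_ = [fk.spec for fk in fitted_kernels]
        self.kernel_weights_ = fit.kernel_weights
        self.dual_coef_ = fit.signed_dual
        self.intercept_ = fit.bias
        self.objective_ = fit.objective
        self.convergence_ = fit.convergence

    # -- prediction ----------------------------------------------------------

    def _standardized_block(self, ds: MultiOmicsDataset, name: str) -> np.ndarray:
        mu, sd, cols = self._scalers[name]
        block = ds.block(name)
        train_block = self.model.dataset.block(name)
        want = [train_block.feature_ids[c] for c in cols]
        index = {fid: j for j, fid in enumerate(block.feature_ids)}
        missing = [fid for fid in want if fid not in index]
        if missing:
            raise KeyError(
                f"block {name!r}: missing feature(s) {missing[:5]}"
                + ("..." if len(missing) > 5 else "")
            )
        X = block.values[:, [index[fid] for fid in want]]
        return (X - mu) / sd

    def decision_function(self, new_data: MultiOmicsDataset) -> np.ndarray:
        """f(x) = sum_i a_i sum_m d_m K_m(x, x_i) + b for each new sample."""
        per_block = {
            name: self._standardized_block(new_data, name) for name in self._scalers
        }
        n_new = new_data.n_samples
        combined = np.zeros((n_new, len(self.dual_coef_)))
        for w, fk in zip(self.kernel_weights_, self._kernels):
            if w:
                combined += w * fk.cross(per_block[fk.spec.block_name])
        return combined @ self.dual_coef_ + self.intercept_

    def predict(self, new_data: MultiOmicsDataset) -> np.ndarray:
        """Signed class labels; a decision value of exactly 0 maps to +1."""
        scores = self.decision_function(new_data)
        return np.where(scores >= 0, 1, -1)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.decision_function(self.model.dataset)

    # -- reporting -----------------------------------------------------------

    def weights_by_block(self) -> dict[str, float]:
        """Total kernel weight per omics block."""
        out: dict[str, float] = {}
        for w, spec in zip(self.kernel_weights_, self.kernel_specs_):
            out[spec.block_name] = out.get(spec.block_name, 0.0) + float(w)
        return out

    def summary(self) -> str:
        rec = self.convergence_
        n_sv = int(np.count_nonzero(self.dual_coef_))
        lines = [
            "Omics-MKL classification results",
            "=" * 58,
            f"No. training samples:  {self.model.dataset.n_samples}",
            f"Selected features:     {len(self.selected_features_)}",
            f"Base kernels:          {len(self.kernel_specs_)}",
            f"SVM cost C:            {self.model.C:g}",
            f"Support vectors:       {n_sv}",
            f"Objective J(d):        {self.objective_:.6f}",
            f"Duality gap:           {rec.final_gap:.3g}"
            f" ({'converged' if rec.converged else 'NOT converged'}, "
            f"{rec.n_iter} weight steps)",
            "-" * 58,
            f"{'block':<18}{'kernel':<12}{'weight':>10}",
            "-" * 58,
        ]
        for w, spec in zip(self.kernel_weights_, self.kernel_specs_):
            lines.append(f"{spec.block_name:<18}{spec.family:<12}{w:>10.4f}")
        counts: dict[str, int] = {}
        for e in self.selected_features_:
            counts[e.ref.block_name] = counts.get(e.ref.block_name, 0) + 1
        lines.append("-" * 58)
        lines.append("selected features per block: " + ", ".join(
            f"{k}={v}" for k, v in counts.items()
        ))
        if rec.warning:
            lines.append(f"warning: {rec.warning}")
        return "\n".join(lines)
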