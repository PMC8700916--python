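"""Per-block Gaussian and polynomial kernels with spherical normalization.

Each omics block contributes two base kernels: a Gaussian
K(x, x') = exp(-||x - x'||^2 / (2 sigma_b^2)) with bandwidth sigma_b set by
the median heuristic (median of the nonzero pairwise training distances),
and a polynomial K(x, x') = (<x, x'> / q + offset)^degree with the inner
product scaled by the block's feature count q so blocks of very different
width remain commensurable.  Every kernel is then spherically normalized,
K(x, x') / sqrt(K(x, x) K(x', x')), giving a unit diagonal; without this the
polynomial kernel on the widest block would dominate any convex combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KERNEL_FAMILIES = ("gaussian", "polynomial")


@dataclass
class KernelSpec:
    """One base kernel: which block it reads and its family/hyperparameters.

    ``bandwidth=None`` requests the median heuristic at build time.
    """

    block_name: str
    family: str
    bandwidth: float | None = None  # gaussian only; None -> median heuristic
    degree: int = 2
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


@dataclass
class KernelMatrix:
    """Normalized Gram matrix over training samples, tagged with its spec."""

    values: np.ndarray
    spec: KernelSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = (A**2).sum(axis=1)[:, None] + (B**2).sum(axis=1)[None, :] - 2 * A @ B.T
    return np.maximum(d, 0.0)


def median_bandwidth(X: np.ndarray) -> float:
    """Median of nonzero pairwise Euclidean distances (median heuristic)."""
    d = np.sqrt(_sq_dists(X, X))
    upper = d[np.triu_indices_from(d, k=1)]
    nz = upper[upper > 0]
    if nz.size == 0:
        return 1.0  # degenerate: all points identical
    return float(np.median(nz))


def _raw_cross(A: np.ndarray, B: np.ndarray, spec: KernelSpec, bandwidth: float) -> np.ndarray:
    if spec.family == "gaussian":
        return np.exp(-_sq_dists(A, B) / (2.0 * bandwidth**2))
    q = A.shape[1]
    return (A @ B.T / q + spec.offset) ** spec.degree


def _raw_diag(A: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.family == "gaussian":
        return np.ones(A.shape[0])
    q = A.shape[1]
    return ((A**2).sum(axis=1) / q + spec.offset) ** spec.degree


class FittedKernel:
    """A base kernel fitted on training rows of one block.

    Stores the training matrix, the resolved bandwidth and the training
    self-similarities so that cross-kernels to new samples are normalized
    consistently with the training Gram matrix.
    """

    def __init__(self, X_train: np.ndarray, spec: KernelSpec) -> None:
        if X_train.shape[0] < 2 or X_train.shape[1] < 1:
            raise ValueError("need >= 2 samples and >= 1 feature")
        self.spec = spec
        self.X_train = np.asarray(X_train, dtype=float)
        if spec.family == "gaussian":
            self.bandwidth = (
                spec.bandwidth if spec.bandwidth is not None
                else median_bandwidth(self.X_train)
            )
        else:
            self.bandwidth = 0.0
        self._train_diag = _raw_diag(self.X_train, spec)

    def gram(self) -> KernelMatrix:
        K = _raw_cross(self.X_train, self.X_train, self.spec, self.bandwidth)
        denom = np.sqrt(np.outer(self._train_diag, self._train_diag))
        K = K / denom
        K = 0.5 * (K + K.T)  # symmetrize away rounding noise
        return KernelMatrix(K, self.spec)

    def cross(self, X_new: np.ndarray) -> np.ndarray:
        """Normalized (n_new, n_train) cross-kernel to new samples."""
        X_new = np.asarray(X_new, dtype=float)
        K = _raw_cross(X_new, self.X_train, self.spec, self.bandwidth)
        denom = np.sqrt(np.outer(_raw_diag(X_new, self.spec), self._train_diag))
        return K / denom


def build_kernel(block_values: np.ndarray, spec: KernelSpec) -> KernelMatrix:
    """Normalized training Gram matrix for one block submatrix."""
    return FittedKernel(np.asarray(block_values, dtype=float), spec).gram()


def combine_kernels(kernels: list[KernelMatrix] | list[np.ndarray], d: np.ndarray) -> np.ndarray:
    """Convex combination sum_m d_m K_m; d must lie on the simplex."""
    d = np.asarray(d, dtype=float)
    mats = [k.values if isinstance(k, KernelMatrix) else np.asarray(k) for k in kernels]
    if len(mats) != d.size:
        raise ValueError("one weight per kernel required")
    if d.min() < 0 or abs(d.sum() - 1.0) > 1e-8:
        raise ValueError("weights must be nonnegative and sum to 1")
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"kernel shape mismatch: {shapes}")
    out = np.zeros(mats[0].shape)
    for w, m in zip(d, mats):
        if w:
            out += w * m
    return out
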