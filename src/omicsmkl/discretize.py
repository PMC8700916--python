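"""Ternary discretization of continuous features for mutual-information work.

Each continuous feature x is coded against its own mean mu and sample
standard deviation sigma: values below mu - alpha*sigma become -1, values in
the closed band [mu - alpha*sigma, mu + alpha*sigma] become 0, values above
become +1.  alpha (default 0.5) controls how wide the "unchanged" band is.
Integer-coded blocks (copy-number gain/loss calls) are already categorical
and pass through untouched.

Band statistics are estimated on training samples only and reused to code
validation samples, so cross-validation never leaks held-out values into the
coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import FeatureBlock, MultiOmicsDataset


@dataclass
class DiscretizationParams:
    """alpha scales the half-width of the zero band; sigma uses the sample
    (n-1) estimator by default (switchable via ``ddof``)."""

    alpha: float = 0.5
    ddof: int = 1
    passthrough_integer_coded: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def discretize_feature(
    x: np.ndarray, params: DiscretizationParams | None = None
) -> np.ndarray:
    """Ternary codes for one feature vector.

    A zero-variance feature codes to all zeros (band boundaries are
    inclusive).  Invariant under positive affine maps of x.
    """
    params = params or DiscretizationParams()
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to estimate the band")
    mu = x.mean()
    sigma = x.std(ddof=params.ddof)
    lo, hi = mu - params.alpha * sigma, mu + params.alpha * sigma
    return np.where(x < lo, -1, np.where(x > hi, 1, 0)).astype(np.int8)


@dataclass
class CategoricalMatrix:
    """Discretized view of a block or joined dataset: small-integer codes,
    one column per feature, sample order matching the source."""

    values: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)


class BlockDiscretizer:
    """Fit the per-feature bands on training rows; transform any rows.

    For integer-coded blocks the transform is the identity (cast to int8
    after clipping to the {-2..2} code set).
    """

    def __init__(self, params: DiscretizationParams | None = None) -> None:
        self.params = params or DiscretizationParams()
        self._lo: np.ndarray | None = None
        self._hi: np.ndarray | None = None
        self._passthrough = False

    def fit(self, block: FeatureBlock) -> "BlockDiscretizer":
        p = self.params
        if block.value_kind == "integer-coded" and p.passthrough_integer_coded:
            self._passthrough = True
            return self
        X = block.values
        mu = X.mean(axis=0)
        sigma = X.std(axis=0, ddof=p.ddof)
        self._lo = mu - p.alpha * sigma
        self._hi = mu + p.alpha * sigma
        return self

    def transform(self, values: np.ndarray) -> np.ndarray:
        if self._passthrough:
            return np.clip(np.rint(values), -2, 2).astype(np.int8)
        if self._lo is None:
            raise RuntimeError("not fitted")
        return np.where(
            values < self._lo, -1, np.where(values > self._hi, 1, 0)
        ).astype(np.int8)


def discretize_block(
    block: FeatureBlock, params: DiscretizationParams | None = None
) -> CategoricalMatrix:
    """Column-wise discretization of one block (fit and transform on the
    same rows)."""
    d = BlockDiscretizer(params).fit(block)
    return CategoricalMatrix(d.transform(block.values), list(block.feature_ids))


class DatasetDiscretizer:
    """Discretize every block of a dataset with training-only statistics.

    ``fit`` on the training dataset; ``transform`` accepts any dataset with
    the same blocks/features (e.g. a validation fold) and returns the joined
    categorical matrix over all blocks, columns in block order.
    """

    def __init__(self, params: DiscretizationParams | None = None) -> None:
        self.params = params or DiscretizationParams()
        self._per_block: dict[str, BlockDiscretizer] = {}
        self._block_order: list[str] = []

    def fit(self, ds: MultiOmicsDataset) -> "DatasetDiscretizer":
        self._per_block = {
            b.name: BlockDiscretizer(self.params).fit(b) for b in ds.blocks
        }
        self._block_order = ds.block_names
        return self

    def transform(self, ds: MultiOmicsDataset) -> CategoricalMatrix:
        if ds.block_names != self._block_order:
            raise ValueError(
                f"block mismatch: fitted on {self._block_order}, got {ds.block_names}"
            )
        parts, ids = [], []
        for b in ds.blocks:
            parts.append(self._per_block[b.name].transform(b.values))
            ids.extend(b.feature_ids)
        return CategoricalMatrix(np.hstack(parts), ids)

    def fit_transform(self, ds: MultiOmicsDataset) -> CategoricalMatrix:
        return self.fit(ds).transform(ds)
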