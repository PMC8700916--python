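"""Synthetic multi-omics generator with known ground-truth signal structure.

Emulates a five-block tumour-staging cohort at desk scale: an integer-coded
copy-number-like block (gain/loss calls in {-2..2}), a [0,1]-bounded
methylation-like block, and unbounded continuous expression / miRNA / protein
blocks.  Class signal is planted as a mean shift on designated *informative*
features; *redundant* features are noisy copies of informative parents with a
target correlation, so that redundancy-penalising feature selection has
something to penalise; all remaining features are pure noise.

The generative model is a pair of class-conditional Gaussians with equal
variance on a latent continuous scale; value-kind transforms (rounding and
clipping for the integer block, a logistic squash for the unit-interval
block) are applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import FeatureBlock, FeatureRef, MultiOmicsDataset


@dataclass
class BlockConfig:
    """Layout of one synthetic block.

    ``effect_size`` is the standardised mean shift (in units of ``noise_sd``)
    between classes on each informative feature; ``redundancy_correlation``
    is the target Pearson correlation between each redundant feature and its
    informative parent on the latent scale.
    """

    name: str
    value_kind: str = "continuous"
    n_features: int = 100
    n_informative: int = 0
    effect_size: float = 0.0
    n_redundant: int = 0
    redundancy_correlation: float = 0.9


@dataclass
class SyntheticConfig:
    n_samples: int = 200
    prevalence_positive: float = 81 / 351
    blocks: list[BlockConfig] = field(default_factory=lambda: luad_mini_blocks())
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence_positive < 1:
            raise ValueError("prevalence_positive must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_pos = round(self.n_samples * self.prevalence_positive)
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ValueError(
                "infeasible config: each class needs at least 2 samples"
            )
        for b in self.blocks:
            if b.n_informative + b.n_redundant > b.n_features:
                raise ValueError(
                    f"block {b.name!r}: n_informative + n_redundant exceeds n_features"
                )
            if b.n_redundant > 0 and b.n_informative == 0:
                raise ValueError(
                    f"block {b.name!r}: redundant features need informative parents"
                )
            if b.n_redundant > 0 and not 0 < b.redundancy_correlation < 1:
                raise ValueError(
                    f"block {b.name!r}: redundancy_correlation must be in (0, 1)"
                )


def luad_mini_blocks() -> list[BlockConfig]:
    """Default "luad-mini" layout: five blocks sized (500, 400, 400, 80, 50)
    mirroring the relative footprint of CNV / methylation / expression /
    miRNA / protein data, with class signal split across the methylation-like
    and expression-like blocks and noise elsewhere."""
    return [
        BlockConfig("CNV", "integer-coded", 500),
        BlockConfig("Methylation", "unit-interval", 400, n_informative=12,
                    effect_size=0.8, n_redundant=6, redundancy_correlation=0.9),
        BlockConfig("GeneExpression", "continuous", 400, n_informative=12,
                    effect_size=0.8, n_redundant=6, redundancy_correlation=0.9),
        BlockConfig("miRNA", "continuous", 80),
        BlockConfig("Protein", "continuous", 50),
    ]


def luad_mini_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default study fixture: n=200 samples at 81/351 prevalence."""
    return replace(SyntheticConfig(seed=seed), **overrides)


@dataclass
class GroundTruth:
    """Planted roles: per block, which features carry signal and which are
    redundant copies (with their parents)."""

    informative: dict[str, list[FeatureRef]]
    redundant: dict[str, list[FeatureRef]]
    parents: dict[FeatureRef, FeatureRef]

    def informative_refs(self) -> list[FeatureRef]:
        return [r for refs in self.informative.values() for r in refs]

    def role_of(self, ref: FeatureRef) -> str:
        if ref in set(self.informative.get(ref.block_name, [])):
            return "informative"
        if ref in set(self.redundant.get(ref.block_name, [])):
            return "redundant"
        return "noise"


def _latent_block(
    rng: np.random.Generator, y: np.ndarray, cfg: BlockConfig, noise_sd: float
) -> np.ndarray:
    """Latent Gaussian block before value-kind transform."""
    n = len(y)
    X = rng.normal(0.0, noise_sd, size=(n, cfg.n_features))
    k = cfg.n_informative
    if k:
        # symmetric shift keeps the pooled mean at zero
        shift = 0.5 * cfg.effect_size * noise_sd
        X[:, :k] += np.where(y[:, None] > 0, shift, -shift)
    if cfg.n_redundant:
        # child = parent + noise, noise variance set so that the population
        # correlation with the parent equals redundancy_correlation; the
        # parent's marginal variance includes the between-class component
        prev = float((y > 0).mean())
        delta = cfg.effect_size * noise_sd
        var_parent = noise_sd**2 + prev * (1 - prev) * delta**2
        rho = cfg.redundancy_correlation
        sd_e = np.sqrt(var_parent * (1 / rho**2 - 1))
        parents = np.arange(cfg.n_redundant) % k
        cols = X[:, parents]
        X[:, k : k + cfg.n_redundant] = cols + rng.normal(
            0.0, sd_e, size=(n, cfg.n_redundant)
        )
    return X


def _apply_value_kind(X: np.ndarray, value_kind: str) -> np.ndarray:
    if value_kind == "integer-coded":
        return np.clip(np.rint(X), -2, 2)
    if value_kind == "unit-interval":
        return 1.0 / (1.0 + np.exp(-X))
    return X


def generate_multiomics(cfg: SyntheticConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Generate a dataset plus its planted ground truth.

    Reproducible: the same config (including seed) yields byte-identical
    matrices.  Labels have exactly ``round(n_samples * prevalence_positive)``
    positives, placed at seeded-random positions.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_pos = round(n * cfg.prevalence_positive)
    y = np.full(n, -1, dtype=int)
    y[rng.permutation(n)[:n_pos]] = 1

    blocks: list[FeatureBlock] = []
    informative: dict[str, list[FeatureRef]] = {}
    redundant: dict[str, list[FeatureRef]] = {}
    parents: dict[FeatureRef, FeatureRef] = {}
    for bc in cfg.blocks:
        lat = _latent_block(rng, y, bc, cfg.noise_sd)
        values = _apply_value_kind(lat, bc.value_kind)
        ids = [f"{bc.name}_f{j:04d}" for j in range(bc.n_features)]
        blocks.append(FeatureBlock(bc.name, values, ids, bc.value_kind))
        informative[bc.name] = [
            FeatureRef(bc.name, ids[j], j) for j in range(bc.n_informative)
        ]
        redundant[bc.name] = [
            FeatureRef(bc.name, ids[bc.n_informative + j], bc.n_informative + j)
            for j in range(bc.n_redundant)
        ]
        for j, child in enumerate(redundant[bc.name]):
            parents[child] = informative[bc.name][j % bc.n_informative]

    sample_ids = [f"S{i:04d}" for i in range(n)]
    ds = MultiOmicsDataset(sample_ids=sample_ids, labels=y, blocks=blocks)
    return ds, GroundTruth(informative, redundant, parents)


def write_ground_truth(gt: GroundTruth, ds: MultiOmicsDataset, path) -> None:
    """TSV of (block, feature_id, role) for every feature."""
    with open(path, "w") as fh:
        fh.write("block\tfeature_id\trole\n")
        for ref in ds.feature_refs():
            fh.write(f"{ref.block_name}\t{ref.feature_id}\t{gt.role_of(ref)}\n")
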