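"""Multi-omics dataset containers and TSV/CSV readers and writers.

A dataset is an ordered collection of omics *blocks* — one sample-by-feature
numeric matrix per molecular data type (copy number, DNA methylation, gene
expression, miRNA, protein) — together with a binary per-sample label
(+1 = late tumour stage T3–T4, -1 = early stage T1–T2).  All blocks share the
same samples in the same order; samples missing from any block are dropped at
load time, mirroring the completeness filter applied to multi-omics cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VALUE_KINDS = ("integer-coded", "unit-interval", "continuous")

#: mapping from label-file stage strings to the signed class code
STAGE_TO_LABEL = {
    "early": -1, "late": +1,
    "t1": -1, "t2": -1, "t3": +1, "t4": +1,
}


@dataclass
class FeatureRef:
    """Pointer to one feature column of one named block."""

    block_name: str
    feature_id: str
    column_index: int

    def __hash__(self) -> int:
        return hash((self.block_name, self.feature_id))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureRef):
            return NotImplemented
        return (self.block_name, self.feature_id) == (other.block_name, other.feature_id)


@dataclass
class FeatureBlock:
    """One omics data type: a samples-by-features real matrix.

    ``value_kind`` declares the value domain: ``integer-coded`` for copy-number
    style gain/loss calls in {-2..2}, ``unit-interval`` for beta-value style
    data in [0, 1], ``continuous`` for unbounded expression-like data.
    """

    name: str
    values: np.ndarray
    feature_ids: list[str]
    value_kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError(f"block {self.name!r}: values must be 2-D")
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"block {self.name!r}: {self.values.shape[1]} columns but "
                f"{len(self.feature_ids)} feature ids"
            )
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"block {self.name!r}: unknown value_kind {self.value_kind!r}")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class MultiOmicsDataset:
    """Aligned multi-omics matrices with binary labels.

    Invariants: sample ids unique; every block has one row per sample, in the
    dataset's sample order; labels take values in {+1, -1} with both classes
    present; (block, feature id) pairs are globally unique.
    """

    sample_ids: list[str]
    labels: np.ndarray
    blocks: list[FeatureBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.labels = np.asarray(self.labels, dtype=int)

    # -- accessors -----------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def block(self, name: str) -> FeatureBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    def feature_refs(self) -> list[FeatureRef]:
        """All features, in block order then column order."""
        refs: list[FeatureRef] = []
        for b in self.blocks:
            refs.extend(
                FeatureRef(b.name, fid, j) for j, fid in enumerate(b.feature_ids)
            )
        return refs

    def resolve(self, ref: FeatureRef) -> np.ndarray:
        """Column of values the reference points to."""
        b = self.block(ref.block_name)
        j = b.feature_ids.index(ref.feature_id)
        return b.values[:, j]

    # -- subsetting ----------------------------------------------------------

    def take(self, indices: Sequence[int] | np.ndarray) -> "MultiOmicsDataset":
        """Row-subset (samples) by positional indices, preserving order."""
        idx = np.asarray(indices, dtype=int)
        return MultiOmicsDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            blocks=[
                FeatureBlock(b.name, b.values[idx], list(b.feature_ids), b.value_kind)
                for b in self.blocks
            ],
        )

    def select_blocks(self, names: Iterable[str]) -> "MultiOmicsDataset":
        names = list(names)
        missing = [n for n in names if n not in self.block_names]
        if missing:
            raise KeyError(f"unknown blocks: {missing}")
        return MultiOmicsDataset(
            sample_ids=list(self.sample_ids),
            labels=self.labels.copy(),
            blocks=[b for b in self.blocks if b.name in names],
        )


def validate_dataset(ds: MultiOmicsDataset) -> list[str]:
    """Check every dataset invariant; return human-readable violations.

    An empty list means the dataset is well formed.  Purely a reporting
    operation — never raises.
    """
    violations: list[str] = []
    ids = ds.sample_ids
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        violations.append(f"duplicate sample ids: {dupes}")
    if len(ds.labels) != len(ids):
        violations.append(
            f"{len(ds.labels)} labels for {len(ids)} samples"
        )
    bad = set(np.unique(ds.labels)) - {-1, 1}
    if bad:
        violations.append(f"labels outside {{+1,-1}}: {sorted(bad)}")
    if len(set(np.unique(ds.labels)) & {-1, 1}) < 2 and len(ids) > 0:
        violations.append("single class: both label values must be present")
    seen: set[tuple[str, str]] = set()
    for b in ds.blocks:
        if b.n_samples != len(ids):
            violations.append(
                f"block {b.name!r}: {b.n_samples} rows for {len(ids)} samples"
            )
        if len(set(b.feature_ids)) != len(b.feature_ids):
            dupes = sorted({f for f in b.feature_ids if b.feature_ids.count(f) > 1})
            violations.append(f"block {b.name!r}: duplicated feature ids {dupes}")
        if not np.isfinite(b.values).all():
            n_bad = int((~np.isfinite(b.values)).sum())
            violations.append(f"block {b.name!r}: {n_bad} missing/non-finite values")
        for fid in set(b.feature_ids):  # cross-block duplicates only
            key = (b.name, fid)
            if key in seen:
                violations.append(f"duplicate (block, feature) pair {key}")
            seen.add(key)
    names = [b.name for b in ds.blocks]
    if len(set(names)) != len(names):
        violations.append(f"duplicate block names: {names}")
    return violations


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# Matrix files: TSV/CSV, UTF-8, header row = feature ids, first column =
# sample id.  Optionally transposed on disk (features as rows).
# Label files: two columns, sample_id <TAB> stage, stage in {early, late} or
# {T1..T4} (T1, T2 -> early -> -1; T3, T4 -> late -> +1).
# Manifest: YAML listing label file and per-block name/path/value_kind.


def _read_matrix(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValueError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                ) from None
        raise
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def read_labels(path: str | Path) -> pd.Series:
    """Labels as a Series of {+1, -1} indexed by sample id, file order kept."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns sample_id<TAB>stage")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "stage"]
    if df.iloc[0, 0].lower() in {"sample_id", "sample"}:  # tolerate a header
        df = df.iloc[1:]
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    stages = df["stage"].str.strip().str.lower()
    unknown = sorted(set(stages) - set(STAGE_TO_LABEL))
    if unknown:
        raise ValueError(
            f"{path}: unknown stage value(s) {unknown}; expected "
            f"early/late or T1..T4"
        )
    return pd.Series(
        [STAGE_TO_LABEL[s] for s in stages],
        index=df["sample_id"].astype(str).to_numpy(),
        dtype=int,
    )


def load_dataset(
    matrix_paths: Mapping[str, str | Path],
    label_path: str | Path,
    value_kinds: Mapping[str, str] | None = None,
    transpose: Mapping[str, bool] | None = None,
) -> MultiOmicsDataset:
    """Assemble a dataset from per-block matrix files and a label file.

    Sample order follows the label file; blocks are re-indexed to it.  Samples
    missing from any block (or unlabelled) are dropped with a logged count.

    Parameters
    ----------
    matrix_paths
        Ordered mapping block name -> matrix file path.
    label_path
        Two-column TSV mapping sample id to stage.
    value_kinds
        Optional mapping block name -> value kind (default ``continuous``).
    transpose
        Optional mapping block name -> bool for feature-by-sample files.
    """
    value_kinds = dict(value_kinds or {})
    transpose = dict(transpose or {})
    labels = read_labels(label_path)

    frames: dict[str, pd.DataFrame] = {}
    common = list(labels.index)
    for name, path in matrix_paths.items():
        df = _read_matrix(path, transpose=transpose.get(name, False))
        frames[name] = df
        here = set(df.index)
        if not (here & set(common)):
            raise ValueError(
                f"block {name!r} ({path}) shares no samples with the label file"
            )
        before = len(common)
        common = [s for s in common if s in here]
        dropped = before - len(common)
        if dropped:
            logger.warning(
                "block %r: dropped %d sample(s) missing from it", name, dropped
            )
    total_dropped = len(labels) - len(common)
    if total_dropped:
        logger.info(
            "retained %d of %d labelled samples present in all blocks",
            len(common), len(labels),
        )

    blocks = [
        FeatureBlock(
            name=name,
            values=frames[name].loc[common].to_numpy(dtype=float),
            feature_ids=list(frames[name].columns),
            value_kind=value_kinds.get(name, "continuous"),
        )
        for name in matrix_paths
    ]
    ds = MultiOmicsDataset(
        sample_ids=common, labels=labels.loc[common].to_numpy(), blocks=blocks
    )
    problems = validate_dataset(ds)
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))
    return ds


def load_dataset_from_manifest(manifest_path: str | Path) -> MultiOmicsDataset:
    """Load via a YAML manifest: ``labels`` path plus a ``blocks`` list of
    ``{name, path, value_kind, transpose}`` entries (paths relative to the
    manifest)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    entries = manifest["blocks"]
    return load_dataset(
        matrix_paths={e["name"]: base / e["path"] for e in entries},
        label_path=base / manifest["labels"],
        value_kinds={e["name"]: e.get("value_kind", "continuous") for e in entries},
        transpose={e["name"]: bool(e.get("transpose", False)) for e in entries},
    )


def write_dataset(ds: MultiOmicsDataset, outdir: str | Path) -> Path:
    """Write per-block TSVs, a label TSV and a manifest; returns manifest path.

    ``load_dataset_from_manifest`` on the result reproduces values and sample
    and feature order exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for b in ds.blocks:
        fname = f"{b.name}.tsv"
        pd.DataFrame(
            b.values, index=pd.Index(ds.sample_ids, name="sample_id"),
            columns=b.feature_ids,
        ).to_csv(outdir / fname, sep="\t", float_format="%.17g")
        entries.append({"name": b.name, "path": fname, "value_kind": b.value_kind})
    with open(outdir / "labels.tsv", "w") as fh:
        for s, y in zip(ds.sample_ids, ds.labels):
            fh.write(f"{s}\t{'late' if y > 0 else 'early'}\n")
    manifest = {"labels": "labels.tsv", "blocks": entries}
    mpath = outdir / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath
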