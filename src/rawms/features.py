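"""Per-sample feature assembly, cohort matrices and constant-feature removal.

A sample's encodings are concatenated in canonical order — MS1 first, then
MS2 windows ascending — either as MS1 alone (``ms1_only``) or MS1 plus all
MS2 windows (``ms1_and_ms2``). Stacking samples gives the cohort matrix,
from which constant features (zero standard deviation, i.e. all entries of
a column exactly equal) are eliminated before classification; encoders
applied to sparse spectra images routinely emit such dead features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .encode import FeatureVector
from .errors import AssemblyError, EmptyMatrixError, ValidationError
from .sources import MS1, Source

__all__ = [
    "SampleFeatures",
    "FeatureMatrix",
    "assemble_sample",
    "build_matrix",
    "drop_constant_features",
    "load_tabular_features",
    "save_tabular_features",
]

MODES = ("ms1_only", "ms1_and_ms2")


@dataclass
class SampleFeatures:
    """One sample's concatenated encoding with its layout.

    ``layout`` lists (source, offset, length) blocks in concatenation
    order, so any input vector can be recovered by slicing.
    """

    sample_id: str
    mode: str
    vector: np.ndarray
    layout: list[tuple[Source, int, int]]

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if len(self.vector) != sum(length for _, _, length in self.layout):
            raise ValidationError("vector length does not match layout")

    def slice(self, source: Source) -> np.ndarray:
        for src, offset, length in self.layout:
            if src == source:
                return self.vector[offset : offset + length]
        raise KeyError(source)


def assemble_sample(
    sample_id: str,
    vectors: Mapping[Source, FeatureVector],
    mode: str = "ms1_and_ms2",
    n_windows: int | None = None,
) -> SampleFeatures:
    """Concatenate one sample's per-source encodings in canonical order.

    ms1_only keeps the MS1 encoding; ms1_and_ms2 appends every window's MS2
    encoding, ascending. A missing window vector is an error (zero-filling
    would fabricate black spectra).
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}")
    if MS1 not in vectors:
        raise AssemblyError(f"sample {sample_id!r}: MS1 vector missing")
    ordered: list[Source] = [MS1]
    if mode == "ms1_and_ms2":
        windows = sorted(src.window for src in vectors if src.level == 2)
        if n_windows is not None:
            expected = list(range(n_windows))
            missing = sorted(set(expected) - set(windows))
            if missing:
                raise AssemblyError(
                    f"sample {sample_id!r}: missing MS2 vector for window(s) {missing}"
                )
            windows = expected
        ordered.extend(Source.ms2(w) for w in windows)

    parts, layout, offset = [], [], 0
    for src in ordered:
        vec = vectors[src].values
        parts.append(vec)
        layout.append((src, offset, len(vec)))
        offset += len(vec)
    return SampleFeatures(sample_id, mode, np.concatenate(parts), layout)


@dataclass
class FeatureMatrix:
    """Cohort matrix: samples x features with binary labels (tumor=1)."""

    sample_ids: list[str]
    labels: np.ndarray
    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    retained_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int).ravel()
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValidationError("sample_ids, labels and rows must agree")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample_ids")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(p)]
        if len(self.feature_names) != p:
            raise ValidationError("feature_names length must match columns")
        if self.retained_mask is not None:
            self.retained_mask = np.asarray(self.retained_mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def retention_fraction(self) -> float:
        if self.retained_mask is None:
            return 1.0
        return self.values.shape[1] / len(self.retained_mask)


def build_matrix(samples: Sequence[SampleFeatures], labels: Mapping[str, int]) -> FeatureMatrix:
    """Stack per-sample vectors (all same mode/layout) into a cohort matrix."""
    if not samples:
        raise ValidationError("no samples")
    first = samples[0]
    for s in samples[1:]:
        if s.mode != first.mode or [l[:1] + l[2:] for l in s.layout] != [
            l[:1] + l[2:] for l in first.layout
        ]:
            raise ValidationError(f"sample {s.sample_id!r} has an inconsistent layout")
    names = [
        f"{src}_f{i}" for src, _, length in first.layout for i in range(length)
    ]
    return FeatureMatrix(
        sample_ids=[s.sample_id for s in samples],
        labels=np.array([labels[s.sample_id] for s in samples]),
        values=np.vstack([s.vector for s in samples]),
        feature_names=names,
    )


def drop_constant_features(
    matrix: FeatureMatrix,
    scope: str = "all_samples",
    train_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Remove features with zero standard deviation.

    Constancy means exact equality of all entries in a column (encodings
    are deterministic floats, so no epsilon is involved). ``scope`` selects
    the rows the test sees: "all_samples" (the default, dataset-level) or
    "train_only" with ``train_ids`` for a leakage-free variant. The result
    carries ``retained_mask`` over the input's columns.
    """
    if matrix.n_samples < 2:
        raise ValidationError("need at least 2 samples to assess constancy")
    if scope == "all_samples":
        rows = matrix.values
    elif scope == "train_only":
        if not train_ids:
            raise ValidationError("train_only scope requires train_ids")
        idx = [matrix.sample_ids.index(s) for s in train_ids]
        rows = matrix.values[idx]
    else:
        raise ValidationError(f"unknown scope {scope!r}")

    mask = ~np.all(rows == rows[0:1, :], axis=0)
    if not mask.any():
        raise EmptyMatrixError("all features are constant; nothing to classify")
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids),
        labels=matrix.labels.copy(),
        values=matrix.values[:, mask],
        feature_names=[n for n, keep in zip(matrix.feature_names, mask) if keep],
        retained_mask=mask,
    )


def save_tabular_features(matrix: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV: sample_id, label, then feature columns."""
    df = pd.DataFrame(matrix.values, columns=matrix.feature_names)
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False)


def load_tabular_features(path) -> FeatureMatrix:
    """Read a CSV feature table (sample_id, label, numeric feature columns).

    This is also the entry point for externally produced comparator
    matrices such as curated peptide or protein quantification tables.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    if df["label"].isna().any():
        raise ValidationError(f"{path.name}: missing label values")
    feature_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    values = df[feature_cols].to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path.name}: non-numeric feature cells") from exc
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path.name}: non-finite feature cells")
    return FeatureMatrix(
        sample_ids=df["sample_id"].astype(str).tolist(),
        labels=df["label"].to_numpy(),
        values=values,
        feature_names=feature_cols,
    )
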