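"""End-to-end glue: runs -> grids -> encodings -> cohort feature matrix.

These helpers chain the rasterize, encode and features stages over a whole
cohort so that classification and benchmarking operate on one call. The
constant-feature elimination and classification protocol stay in their own
modules; this layer only orchestrates.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .classify import EvaluationResult, train_and_evaluate
from .encode import encode_grid
from .features import (
    FeatureMatrix,
    assemble_sample,
    build_matrix,
    drop_constant_features,
)
from .rasterize import RasterConfig, rasterize_run
from .spectra_io import MsRun, validate_window_scheme

__all__ = ["encode_run", "cohort_feature_matrix", "evaluate_cohort"]


def encode_run(run: MsRun, encoder, raster_config: RasterConfig | None = None,
               transform: str = "linear_max") -> dict:
    """Rasterize and encode every scan series of one run, keyed by source."""
    grids = rasterize_run(run, raster_config)
    return {g.source: encode_grid(g, encoder, transform) for g in grids}


def cohort_feature_matrix(
    runs: Sequence[MsRun],
    labels: Mapping[str, int] | pd.DataFrame,
    encoder,
    mode: str = "ms1_and_ms2",
    raster_config: RasterConfig | None = None,
    transform: str = "linear_max",
    drop_constants: bool = True,
) -> FeatureMatrix:
    """Encode a cohort into a (samples x features) matrix.

    Verifies all runs share one isolation-window scheme, concatenates each
    sample's encodings in canonical order for ``mode`` and, by default,
    removes constant features at dataset level.
    """
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["sample_id"].astype(str), labels["label"].astype(int)))
    scheme = validate_window_scheme(runs)
    samples = []
    for run in runs:
        vectors = encode_run(run, encoder, raster_config, transform)
        samples.append(assemble_sample(run.run_id, vectors, mode, n_windows=len(scheme)))
    matrix = build_matrix(samples, labels)
    if drop_constants:
        matrix = drop_constant_features(matrix)
    return matrix


def evaluate_cohort(
    runs: Sequence[MsRun],
    labels,
    encoder,
    mode: str = "ms1_and_ms2",
    classifier: str = "logreg",
    raster_config: RasterConfig | None = None,
    transform: str = "linear_max",
    seed: int = 0,
    **protocol_kwargs,
) -> EvaluationResult:
    """Full pipeline for one configuration: encode, assemble, classify."""
    raster_config = raster_config or RasterConfig()
    matrix = cohort_feature_matrix(
        runs, labels, encoder, mode=mode, raster_config=raster_config, transform=transform
    )
    descriptor = {
        "resolution": raster_config.grid_size,
        "encoder": encoder.spec.name,
        "mode": mode,
        "classifier": classifier,
    }
    return train_and_evaluate(
        matrix, classifier=classifier, seed=seed, descriptor=descriptor, **protocol_kwargs
    )
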