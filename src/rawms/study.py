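"""Canonical end-to-end study harness over synthetic cohorts.

One master seed drives everything: the cohort generator, the encoder
projection and the evaluation protocol each receive a seed derived from
the master seed and a stage label, so a study condition is one integer
away from exact reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import EvaluationResult, train_and_evaluate
from .encode import reference_encoder
from .features import assemble_sample, build_matrix, drop_constant_features
from .pipeline import encode_run
from .rasterize import RasterConfig
from .synthetic_data import SyntheticCohortConfig, generate_cohort
from .util import derive_seed

__all__ = ["StudyCondition", "encode_condition_cohort", "run_condition"]


@dataclass(frozen=True)
class StudyCondition:
    """One synthetic study condition: cohort signal + pipeline configuration."""

    fold_change: float = 4.0
    signal_location: str = "ms1_and_ms2"
    mode: str = "ms1_and_ms2"
    classifier: str = "logreg"
    n_per_class: int = 30
    n_windows: int = 10
    grid_size: int = 512
    encoder_dim: int = 256
    transform: str = "linear_max"


def encode_condition_cohort(condition: StudyCondition, master_seed: int) -> dict:
    """Generate and encode one cohort; return a feature matrix per input mode.

    Every run is rasterized and encoded exactly once; the two input modes
    (ms1_only, ms1_and_ms2) are different concatenations of the same
    per-source encodings. Constant features are removed per mode at
    dataset level.
    """
    config = SyntheticCohortConfig(
        n_per_class=condition.n_per_class,
        n_windows=condition.n_windows,
        seed=derive_seed(master_seed, "cohort"),
    ).with_signal(condition.fold_change, condition.signal_location)
    runs, labels_df = generate_cohort(config)
    labels = dict(zip(labels_df["sample_id"], labels_df["label"]))
    encoder = reference_encoder(
        seed=derive_seed(master_seed, "encoder"), output_dim=condition.encoder_dim
    )
    raster_config = RasterConfig(grid_size=condition.grid_size)

    encodings = [
        (run.run_id, encode_run(run, encoder, raster_config, condition.transform))
        for run in runs
    ]
    matrices = {}
    for mode in ("ms1_only", "ms1_and_ms2"):
        samples = [
            assemble_sample(run_id, vectors, mode, n_windows=condition.n_windows)
            for run_id, vectors in encodings
        ]
        matrices[mode] = drop_constant_features(build_matrix(samples, labels))
    return matrices


def run_condition(
    condition: StudyCondition, master_seed: int, matrices: dict | None = None
) -> EvaluationResult:
    """Run the full pipeline for one condition and master seed.

    ``matrices`` may carry the output of :func:`encode_condition_cohort`
    for callers evaluating several modes or classifiers on one cohort.
    """
    if matrices is None:
        matrices = encode_condition_cohort(condition, master_seed)
    return train_and_evaluate(
        matrices[condition.mode],
        classifier=condition.classifier,
        seed=derive_seed(master_seed, "evaluate"),
        descriptor={
            "fold_change": condition.fold_change,
            "signal_location": condition.signal_location,
            "mode": condition.mode,
            "classifier": condition.classifier,
            "resolution": condition.grid_size,
        },
    )
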