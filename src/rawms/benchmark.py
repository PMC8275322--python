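"""Configuration sweeps and the comparison statistics between them.

A sweep evaluates every (resolution x encoder x input mode x classifier)
configuration on one cohort with per-configuration derived seeds and
tabulates held-out AUCs. Summaries follow the benchmarking protocol:
per-encoder median/mean/std of AUC pooled over classifiers and
resolutions, one-sided paired t-tests between matched configuration pairs
(e.g. ms1_and_ms2 vs ms1_only, or the two grid resolutions), and Spearman
rank correlation between paired AUC sequences.
"""

from __future__ import annotations

import traceback
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateTestError, ValidationError
from .pipeline import cohort_feature_matrix
from .classify import train_and_evaluate
from .rasterize import RasterConfig
from .util import derive_seed

__all__ = [
    "run_sweep",
    "summarize_by_encoder",
    "paired_onesided_ttest",
    "spearman_rank_corr",
    "paired_mode_aucs",
]

MODES = ("ms1_only", "ms1_and_ms2")


def run_sweep(
    runs,
    labels,
    encoders: Mapping[str, object],
    resolutions: Sequence[int] = (512,),
    modes: Sequence[str] = MODES,
    classifiers: Sequence[str] = ("logreg", "svc", "random_forest", "gradient_boosted_trees"),
    transform: str = "linear_max",
    seed: int = 0,
    rt_policy: str = "per_run_minmax",
) -> pd.DataFrame:
    """Evaluate every configuration; one row per (resolution, encoder, mode, classifier).

    Encoding happens once per (resolution, encoder); each classification
    draws its own seed from the master seed and the configuration key, so
    rerunning with the same master seed reproduces the table exactly.
    Failing configurations are recorded in the ``error`` column and the
    sweep continues. Rows are ordered by descending per-encoder median AUC.
    """
    if not encoders:
        raise ConfigError("need at least one encoder")
    rows = []
    for resolution in resolutions:
        raster_config = RasterConfig(grid_size=resolution, rt_policy=rt_policy)
        for enc_name, encoder in encoders.items():
            matrices = {}
            try:
                for mode in modes:
                    matrices[mode] = cohort_feature_matrix(
                        runs, labels, encoder, mode=mode,
                        raster_config=raster_config, transform=transform,
                    )
            except Exception as exc:  # noqa: BLE001 - record and continue
                for mode in modes:
                    for classifier in classifiers:
                        rows.append(_error_row(resolution, enc_name, mode, classifier, exc))
                continue
            for mode in modes:
                for classifier in classifiers:
                    key = f"{resolution}/{enc_name}/{mode}/{classifier}"
                    try:
                        result = train_and_evaluate(
                            matrices[mode],
                            classifier=classifier,
                            seed=derive_seed(seed, key),
                            descriptor={
                                "resolution": resolution,
                                "encoder": enc_name,
                                "mode": mode,
                                "classifier": classifier,
                            },
                        )
                        row = {
                            "resolution": resolution,
                            "encoder": enc_name,
                            "mode": mode,
                            "classifier": classifier,
                            "auc": result.metrics.auc,
                            "cv_auc": result.cv_auc,
                            "error": "",
                        }
                        row.update(
                            {
                                k: v
                                for k, v in result.metrics.as_dict().items()
                                if k != "auc"
                            }
                        )
                        rows.append(row)
                    except Exception as exc:  # noqa: BLE001
                        traceback.clear_frames(exc.__traceback__)
                        rows.append(_error_row(resolution, enc_name, mode, classifier, exc))

    table = pd.DataFrame(rows)
    medians = table.groupby("encoder")["auc"].median()
    table["_encoder_median"] = table["encoder"].map(medians)
    table = table.sort_values(
        ["_encoder_median", "encoder", "resolution", "mode", "classifier"],
        ascending=[False, True, True, True, True],
    ).drop(columns="_encoder_median").reset_index(drop=True)
    return table


def _error_row(resolution, encoder, mode, classifier, exc) -> dict:
    return {
        "resolution": resolution,
        "encoder": encoder,
        "mode": mode,
        "classifier": classifier,
        "auc": np.nan,
        "cv_auc": np.nan,
        "error": f"{type(exc).__name__}: {exc}",
    }


def summarize_by_encoder(table: pd.DataFrame, mode: str | None = None) -> pd.DataFrame:
    """Median, mean and sample std of AUC per encoder.

    Pools rows over classifiers and resolutions (optionally restricted to
    one input mode); a single-row group reports std 0 with its n flagged.
    """
    if table.empty:
        raise ValidationError("empty sweep table")
    rows = table if mode is None else table[table["mode"] == mode]
    groups = rows.dropna(subset=["auc"]).groupby("encoder")["auc"]
    summary = groups.agg(
        median_auc="median",
        mean_auc="mean",
        std_auc=lambda s: float(s.std(ddof=1)) if len(s) > 1 else 0.0,
        n="count",
    ).reset_index()
    return summary.sort_values("median_auc", ascending=False).reset_index(drop=True)


def paired_mode_aucs(
    table: pd.DataFrame, contrast: str = "mode", a: str = "ms1_and_ms2", b: str = "ms1_only"
) -> tuple[np.ndarray, np.ndarray]:
    """Extract matched AUC pairs differing only in one configuration field.

    ``contrast`` names the field (``mode`` or ``resolution``); the
    remaining configuration columns form the pairing key.
    """
    keys = [c for c in ("resolution", "encoder", "mode", "classifier") if c != contrast]
    va = table[table[contrast].astype(str) == str(a)].set_index(keys)["auc"]
    vb = table[table[contrast].astype(str) == str(b)].set_index(keys)["auc"]
    common = va.index.intersection(vb.index)
    return va.loc[common].to_numpy(), vb.loc[common].to_numpy()


def paired_onesided_ttest(a, b) -> tuple[float, float]:
    """Classical paired t-test of H1: mean(a - b) > 0.

    Returns (t, one-sided p). Zero-variance differences (including a == b
    exactly) make the statistic undefined and raise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 3:
        raise ValidationError("need matched sequences of equal length >= 3")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("differences have zero variance; t is undefined")
    n = len(d)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(stats.t.sf(t, df=n - 1))
    return t, p


def spearman_rank_corr(a, b) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 3:
        raise ValidationError("need sequences of equal length >= 3")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise DegenerateTestError("rank correlation undefined for a constant sequence")
    ra = stats.rankdata(a)
    rb = stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])
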