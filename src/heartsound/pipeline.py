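"""End-to-end orchestration: recording -> cycles -> features -> diagnosis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifier as clf
from . import segmentation, spectral
from .preprocess import REFERENCE_FS, SignalTrace, bandlimit, load_recording, normalize
from .spectral import FEATURE_NAMES


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline, at their reference defaults.

    ``half_width``/``window_length`` of None means "scale with the sampling
    rate" (50 ms and ~1 s; 2205 and 44101 samples at 44.1 kHz).
    """

    fs_target: int | None = REFERENCE_FS
    half_width: int | None = None
    window_length: int | None = None
    l1: int = spectral.DEFAULT_L1
    l2: int = spectral.DEFAULT_L2
    swap_windows: bool = False
    thv: tuple = spectral.DEFAULT_THV
    k: int = 7
    regularization: float = 0.01
    max_iter: int = 1000
    beta_grid: np.ndarray = field(default_factory=lambda: clf.DEFAULT_BETA_GRID.copy())
    seed: int = 0


def preprocess_trace(trace: SignalTrace) -> SignalTrace:
    return normalize(bandlimit(trace))


def extract_features(
    trace: SignalTrace, config: PipelineConfig | None = None, *, preprocessed: bool = False
) -> tuple[pd.DataFrame, list]:
    """Segment a trace and compute the per-cycle 8-feature table.

    Returns (feature table with the canonical column names, cycle boundaries).
    """
    config = config or PipelineConfig()
    if not preprocessed:
        trace = preprocess_trace(trace)
    boundaries, cycles = segmentation.segment_recording(
        trace, config.half_width, config.window_length
    )
    rows = [
        spectral.feature_vector(
            cs1, cs2, config.l1, config.l2, config.thv, swap_windows=config.swap_windows
        )
        for cs1, cs2 in cycles
    ]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES)), boundaries


def features_from_file(path, config: PipelineConfig | None = None):
    config = config or PipelineConfig()
    return extract_features(load_recording(path, target_fs=config.fs_target), config)


def train_pipeline(
    features: pd.DataFrame,
    labels,
    config: PipelineConfig | None = None,
) -> clf.ClassifierModel:
    """Fit PCA + GMM + per-class confidence levels on a labelled feature table.

    ``features`` holds the 8 canonical columns; components are matched to the
    supplied class labels and the confidence levels selected by the grid sweep.
    The sweep table is stored in the model metadata.
    """
    config = config or PipelineConfig()
    ff = np.asarray(features[list(FEATURE_NAMES)], dtype=float)
    labels = np.asarray(labels)
    pca = spectral.fit_pca(ff)
    gamma = spectral.project(ff, pca, m=3)
    comps = clf.fit_gmm(
        gamma,
        k=config.k,
        regularization=config.regularization,
        max_iter=config.max_iter,
        seed=config.seed,
        labels=labels,
    )
    beta0 = np.full(len(comps), 0.79)
    model = clf.ClassifierModel(
        comps, beta0, np.array([clf.chi2_inverse(b) for b in beta0]), pca,
        metadata={"seed": config.seed, "regularization": config.regularization,
                  "max_iter": config.max_iter},
    )
    beta, sweep = clf.select_beta(model, gamma, labels, config.beta_grid)
    model = model.with_beta(beta)
    model.metadata["beta_sweep"] = sweep.to_dict()
    return model


def project_features(features, model: clf.ClassifierModel) -> np.ndarray:
    """8-feature rows -> 3-D diagnostic features via the model's PCA constants."""
    if model.pca is None:
        raise clf.DataError("model carries no PCA constants")
    if isinstance(features, pd.DataFrame):
        features = np.asarray(features[list(FEATURE_NAMES)], dtype=float)
    return spectral.project(features, model.pca, m=3)


def classify_features(features, model: clf.ClassifierModel) -> np.ndarray:
    return clf.classify_batch(project_features(features, model), model)


def classify_recording(
    trace: SignalTrace, model: clf.ClassifierModel, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-cycle diagnosis of one recording (label may be "unknown")."""
    config = config or PipelineConfig()
    features, boundaries = extract_features(trace, config)
    labels = classify_features(features, model)
    out = features.copy()
    out.insert(0, "cycle_index", np.arange(len(labels)))
    out["label"] = labels
    return out
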