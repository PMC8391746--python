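"""End-to-end glue: dataset -> conditioned windows -> features -> model
-> thresholds -> reports.

This is the programmatic face of the tool: :func:`run_benchmark`
executes the whole semisupervised workflow on the synthetic benchmark
(train the isolation forest on unlabeled windows, calibrate the two
grade thresholds on the labeled validation split, evaluate on the held
out test split) and returns every intermediate artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import iforest
from .calibrate import QualityThresholds, classify, find_thresholds
from .config import PipelineConfig
from .evaluate import EvalReport, score_report
from .features import feature_names, feature_vector
from .preprocess import condition_window, segment_windows
from .records import SignalRecord
from .synth import DatasetConfig, SyntheticDataset, make_dataset

__all__ = ["extract_features", "SplitArrays", "BenchmarkResult", "run_benchmark"]


def extract_features(records_or_windows, stride_s: float | None = None):
    """Condition and featurize records or raw windows.

    Returns (X, flatline mask, keys) where keys are (record_id, start_s)
    pairs aligned with the rows of X.
    """
    windows = []
    for item in records_or_windows:
        if isinstance(item, SignalRecord):
            windows.extend(segment_windows(item, stride_s))
        else:
            windows.append(item)
    conditioned = [condition_window(w) for w in windows]
    X = np.vstack([feature_vector(w) for w in conditioned])
    flat = np.array([w.flags.get("flatline", False) for w in conditioned])
    keys = [w.key for w in conditioned]
    return X, flat, keys


@dataclass
class SplitArrays:
    """Scores, rule labels and flatline flags of one labeled split."""

    scores: np.ndarray
    labels: np.ndarray
    flatline: np.ndarray

    def predictions(self, thresholds: QualityThresholds) -> np.ndarray:
        return classify(self.scores, thresholds, flatline=self.flatline)


@dataclass
class BenchmarkResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    model: iforest.IsolationForestModel
    thresholds: QualityThresholds
    validation: SplitArrays
    test: SplitArrays
    validation_report: EvalReport
    test_report: EvalReport


def _split_arrays(windows, model) -> SplitArrays:
    X, flat, _ = extract_features([w.record for w in windows])
    return SplitArrays(
        scores=model.score(X),
        labels=np.array([w.grade for w in windows], dtype=int),
        flatline=flat,
    )


def run_benchmark(config: PipelineConfig | None = None, seed: int | None = None) -> BenchmarkResult:
    """Run the full semisupervised workflow on the synthetic benchmark."""
    config = config or PipelineConfig()
    if seed is not None:
        config.seed = seed
    ds_config = DatasetConfig(
        kind=config.kind, fs=config.fs,
        n_train=config.n_train, n_validation=config.n_validation, n_test=config.n_test,
        train_mix=config.train_mix, validation_mix=config.validation_mix,
        test_mix=config.test_mix, seed=config.seed,
    )
    dataset = make_dataset(ds_config)

    X_train, _, _ = extract_features([w.record for w in dataset.train])
    model = iforest.fit(
        X_train,
        n_trees=config.n_trees, psi=config.psi,
        contamination=config.contamination, seed=config.seed,
        feature_names=feature_names(config.kind),
    )

    val = _split_arrays(dataset.validation, model)
    thresholds = find_thresholds(val.scores, val.labels)
    model.calibration = thresholds.to_dict()
    test = _split_arrays(dataset.test, model)

    return BenchmarkResult(
        config=config, dataset=dataset, model=model, thresholds=thresholds,
        validation=val, test=test,
        validation_report=score_report(val.labels, val.predictions(thresholds)),
        test_report=score_report(test.labels, test.predictions(thresholds)),
    )
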