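"""Core in-memory containers shared across the pipeline.

Labels are encoded ``0`` = normal, ``1`` = hypertensive everywhere.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

LABEL_NORMAL = 0
LABEL_HYPER = 1
LABEL_NAMES = {LABEL_NORMAL: "normal", LABEL_HYPER: "hypertensive"}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


@dataclass
class BCGRecord:
    """One subject's raw ballistocardiograph recording.

    ``channels`` is ``(n_channels, n_samples)``; mattress systems expose one
    or two hydraulic pressure channels. ``demographics`` may carry age (yr),
    BMI (kg/m^2), heart rate (bpm) and systolic/diastolic pressure (mmHg).
    """

    subject_id: str
    channels: np.ndarray
    fs: float
    label: int
    demographics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.label not in LABEL_NAMES:
            raise ValueError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def primary(self) -> np.ndarray:
        """First channel; the default input to single-channel stages."""
        return self.channels[0]


@dataclass
class SegmentSet:
    """Fixed-length windows cut from one or more records.

    Rows of ``segments`` are ``(n_segments, segment_length)``; ``labels`` and
    ``subject_ids`` carry per-segment class and provenance.
    """

    segments: np.ndarray
    fs: float
    labels: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != self.segments.shape[0]:
            raise ValueError("labels length must match number of segments")
        if len(self.subject_ids) != self.segments.shape[0]:
            raise ValueError("subject_ids length must match number of segments")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_length(self) -> int:
        return self.segments.shape[1]


@dataclass
class FeatureTable:
    """Samples x features matrix with names and labels.

    The lingua franca between extraction, selection and classification.
    ``provenance`` records the producing stage and its parameters.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureTable":
        """Column-subset view as a new table."""
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, m in zip(self.feature_names, mask) if m]
        return FeatureTable(
            self.values[:, mask],
            names,
            self.labels.copy(),
            dict(self.provenance),
            list(self.subject_ids) if self.subject_ids is not None else None,
        )

    def subset_rows(self, rows: np.ndarray) -> "FeatureTable":
        rows = np.asarray(rows)
        ids = None
        if self.subject_ids is not None:
            ids = [self.subject_ids[i] for i in np.atleast_1d(rows)]
        return FeatureTable(
            self.values[rows], list(self.feature_names), self.labels[rows],
            dict(self.provenance), ids,
        )


@dataclass
class SelectionMask:
    """Binary feature-inclusion vector with its selection ratio and fitness."""

    mask: np.ndarray
    fsr: float
    fitness: float
    selector: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.sum() < 1:
            raise ValueError("mask must select at least one feature")
        if not (0 < self.fsr <= 1):
            raise ValueError(f"fsr must lie in (0, 1], got {self.fsr}")


@dataclass
class ConfusionMatrix:
    """2x2 counts with hypertensive as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )
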