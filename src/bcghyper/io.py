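"""Cohort I/O, ICA artifact cleaning, windowing and standardization."""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import FastICA

from .containers import NAME_TO_LABEL, BCGRecord, FeatureTable, SegmentSet

logger = logging.getLogger(__name__)

_DEMO_KEYS = ("age", "bmi", "hr", "sbp", "dbp")


def read_cohort(manifest_path: str | Path) -> list[BCGRecord]:
    """Load records listed in a manifest.

    The manifest is delimited text with header
    ``subject_id,file,label,fs[,age,bmi,hr,sbp,dbp]``; waveform files are
    headerless one- or two-column delimited text, one sample per row,
    resolved relative to the manifest's directory. Labels are serialized
    as ``normal``/``hypertensive``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "file", "label", "fs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    records: list[BCGRecord] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.subject_id)
        wav_path = manifest_path.parent / str(row.file)
        if not wav_path.exists():
            raise FileNotFoundError(
                f"waveform file for subject {sid!r} not found "
                f"(manifest line {line_no}): {wav_path}"
            )
        label_name = str(row.label).strip().lower()
        if label_name not in NAME_TO_LABEL:
            raise ValueError(
                f"manifest line {line_no}: unknown label {row.label!r} for subject {sid!r}"
            )
        try:
            data = np.loadtxt(wav_path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(
                f"subject {sid!r}: could not parse waveform {wav_path}: {exc}"
            ) from exc
        demographics = {}
        for key in _DEMO_KEYS:
            if hasattr(row, key) and np.isfinite(getattr(row, key)):
                demographics[key] = float(getattr(row, key))
        records.append(
            BCGRecord(
                subject_id=sid,
                channels=data.T,
                fs=float(row.fs),
                label=NAME_TO_LABEL[label_name],
                demographics=demographics,
            )
        )
    return records


def ica_clean(
    record: BCGRecord,
    n_components: int | None = None,
    kurtosis_threshold: float = 10.0,
    seed: int = 0,
) -> BCGRecord:
    """Remove spiky artifact components by FastICA unmixing.

    Channels are unmixed, components whose excess kurtosis exceeds
    ``kurtosis_threshold`` are zeroed (heartbeat trains are far less
    leptokurtic than motion/spike artifacts), and the remaining sources are
    re-projected to the sensor space. Single-channel records pass through
    unchanged with a logged warning.
    """
    if record.n_channels < 2:
        logger.warning(
            "ica_clean: record %s has a single channel; pass-through", record.subject_id
        )
        return record
    if n_components is None:
        n_components = record.n_channels
    if n_components > record.n_channels:
        raise ValueError(
            f"n_components={n_components} exceeds channel count {record.n_channels}"
        )
    X = record.channels.T  # samples x channels
    sds = X.std(axis=0)
    if np.any(sds == 0):
        raise np.linalg.LinAlgError(
            f"record {record.subject_id}: zero-variance channel, ICA is degenerate"
        )
    ica = FastICA(n_components=n_components, random_state=seed, whiten="unit-variance")
    sources = ica.fit_transform(X)
    kurt = stats.kurtosis(sources, axis=0, fisher=True)
    artifact = kurt > kurtosis_threshold
    if artifact.any():
        logger.info(
            "ica_clean: record %s, zeroing %d/%d components (kurtosis %s)",
            record.subject_id, int(artifact.sum()), n_components, np.round(kurt, 2),
        )
    sources = sources.copy()
    sources[:, artifact] = 0.0
    cleaned = ica.inverse_transform(sources)
    return BCGRecord(
        subject_id=record.subject_id,
        channels=cleaned.T,
        fs=record.fs,
        label=record.label,
        demographics=dict(record.demographics),
    )


def segment(record: BCGRecord, window_seconds: float) -> SegmentSet:
    """Cut the primary channel into non-overlapping fixed windows.

    The trailing partial window is dropped; every segment inherits the
    record's label and subject id. Raises if the record is shorter than a
    single window.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    length = int(round(window_seconds * record.fs))
    n_windows = record.n_samples // length
    if n_windows < 1:
        raise ValueError(
            f"record {record.subject_id} has {record.n_samples} samples, "
            f"shorter than one {length}-sample window"
        )
    sig = record.primary[: n_windows * length]
    return SegmentSet(
        segments=sig.reshape(n_windows, length),
        fs=record.fs,
        labels=np.full(n_windows, record.label),
        subject_ids=[record.subject_id] * n_windows,
    )


def segment_cohort(records: list[BCGRecord], window_seconds: float) -> SegmentSet:
    """Concatenate per-record segmentations into one set."""
    parts = [segment(r, window_seconds) for r in records]
    return SegmentSet(
        segments=np.vstack([p.segments for p in parts]),
        fs=records[0].fs,
        labels=np.concatenate([p.labels for p in parts]),
        subject_ids=[sid for p in parts for sid in p.subject_ids],
    )


def standardize(
    table: FeatureTable, fit_rows: np.ndarray | None = None
) -> tuple[FeatureTable, dict[str, np.ndarray]]:
    """Z-score each column using statistics from ``fit_rows`` only.

    Returns the transformed table and the ``{"mean", "sd"}`` scaler
    parameters so test folds can be transformed without refitting (no CV
    leakage). Zero-SD columns are mapped to 0 with a warning.
    """
    if fit_rows is None:
        fit_rows = np.arange(table.n_samples)
    fit_rows = np.asarray(fit_rows)
    if len(fit_rows) == 0:
        raise ValueError("fit_rows must be non-empty")
    mean = table.values[fit_rows].mean(axis=0)
    sd = table.values[fit_rows].std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning("standardize: %d constant column(s) mapped to 0", int(zero.sum()))
    params = {"mean": mean, "sd": sd}
    return apply_standardize(table, params), params


def apply_standardize(table: FeatureTable, params: dict[str, np.ndarray]) -> FeatureTable:
    """Apply previously fitted z-score parameters."""
    sd = params["sd"].copy()
    safe_sd = np.where(sd == 0, 1.0, sd)
    values = (table.values - params["mean"]) / safe_sd
    values[:, sd == 0] = 0.0
    prov = dict(table.provenance)
    prov["standardized"] = True
    return FeatureTable(
        values, list(table.feature_names), table.labels.copy(), prov,
        list(table.subject_ids) if table.subject_ids is not None else None,
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Serialize as delimited text: header of feature names + trailing label column."""
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df["label"] = table.labels
    if table.subject_ids is not None:
        df["subject_id"] = table.subject_ids
    df.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    df = pd.read_csv(path)
    sids = df.pop("subject_id").astype(str).tolist() if "subject_id" in df else None
    labels = df.pop("label").to_numpy()
    return FeatureTable(
        df.to_numpy(float), list(df.columns), labels,
        provenance={"source": str(path)}, subject_ids=sids,
    )
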