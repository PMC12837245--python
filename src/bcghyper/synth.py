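"""Synthetic two-class BCG cohorts and labeled feature tables.

The cohort generator emulates mattress-sensor ballistocardiography: 100 Hz
sampling, 5-minute recordings, heartbeat pulses placed by a per-subject
inter-beat-interval process, a sinusoidal respiratory baseline and additive
sensor noise. Class contrast follows the published cohort heart rates
(hypertensive 77.1 +- 9.2 bpm vs normal 73.6 +- 8.3 bpm) plus a pulse
amplitude/width contrast standing in for the (unknown) morphological
differences between groups.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from pydantic import BaseModel, model_validator

from .containers import FeatureTable, LABEL_HYPER, LABEL_NAMES, LABEL_NORMAL, BCGRecord


class SynthCohortConfig(BaseModel):
    """Study conditions for a synthetic cohort.

    Heart-rate means/SDs default to the published hypertensive and control
    group statistics; ``pulse_amp_ratio`` scales hypertensive beat amplitude
    (width shrinks by ``1/sqrt(ratio)`` so a ratio of 1 leaves the two class
    distributions identical).
    """

    n_normal: int = 40
    n_hyper: int = 40
    fs: float = 100.0
    duration: float = 300.0
    hr_mean_normal: float = 73.6
    hr_sd_normal: float = 8.3
    hr_mean_hyper: float = 77.1
    hr_sd_hyper: float = 9.2
    pulse_amp_ratio: float = 1.3
    resp_freq: float = 0.25
    resp_amp: float = 0.3
    noise_sd: float = 0.1
    ibi_jitter: float = 0.03
    n_channels: int = 1
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthCohortConfig":
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.n_normal < 1 or self.n_hyper < 1:
            raise ValueError("need at least one subject per class")
        if self.hr_sd_normal < 0 or self.hr_sd_hyper < 0:
            raise ValueError("heart-rate SDs must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_channels not in (1, 2):
            raise ValueError("n_channels must be 1 or 2")
        return self


class SynthTableConfig(BaseModel):
    """Labeled Gaussian feature table with known informative columns."""

    n_samples: int = 200
    d_informative: int = 5
    d_noise: int = 15
    effect_size: float = 2.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SynthTableConfig":
        if self.d_informative < 1:
            raise ValueError("d_informative must be >= 1")
        if self.d_noise < 0:
            raise ValueError("d_noise must be non-negative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        return self


def _beat_pulse(fs: float, width_s: float, amp: float, n_cycles: float = 3.0) -> np.ndarray:
    """Gaussian-windowed sinusoid standing in for the I-J-K complex."""
    half = width_s / 2.0
    t = np.arange(-half, half, 1.0 / fs)
    carrier_hz = n_cycles / width_s
    return amp * np.exp(-0.5 * (t / (width_s / 4.0)) ** 2) * np.sin(2 * np.pi * carrier_hz * t)


def _render_record(rng: np.random.Generator, cfg: SynthCohortConfig, label: int) -> np.ndarray:
    n = int(round(cfg.duration * cfg.fs))
    if label == LABEL_HYPER:
        hr = rng.normal(cfg.hr_mean_hyper, cfg.hr_sd_hyper)
        amp = cfg.pulse_amp_ratio
        width = 0.25 / np.sqrt(cfg.pulse_amp_ratio)
    else:
        hr = rng.normal(cfg.hr_mean_normal, cfg.hr_sd_normal)
        amp = 1.0
        width = 0.25
    hr = float(np.clip(hr, 30.0, 180.0))
    mean_ibi = 60.0 / hr

    signal = np.zeros(n)
    pulse = _beat_pulse(cfg.fs, width, amp)
    # place beats until the window is filled; 3% per-beat IBI jitter
    t = rng.uniform(0.0, mean_ibi)
    while t < cfg.duration:
        i0 = int(round(t * cfg.fs))
        seg = pulse[: max(0, min(len(pulse), n - i0))]
        signal[i0 : i0 + len(seg)] += seg
        t += mean_ibi * (1.0 + cfg.ibi_jitter * rng.standard_normal())

    tt = np.arange(n) / cfg.fs
    phase = rng.uniform(0, 2 * np.pi)
    signal += cfg.resp_amp * np.sin(2 * np.pi * cfg.resp_freq * tt + phase)
    if cfg.noise_sd > 0:
        signal += cfg.noise_sd * rng.standard_normal(n)
    return signal


def generate_bcg_cohort(config: SynthCohortConfig) -> list[BCGRecord]:
    """Generate a labeled synthetic cohort, deterministic given ``config.seed``.

    Each record carries ``duration * fs`` samples per channel. A second
    channel, when requested, is an attenuated copy with independent noise
    (leg-sensor analogue).
    """
    rng = np.random.default_rng(config.seed)
    records: list[BCGRecord] = []
    labels = [LABEL_NORMAL] * config.n_normal + [LABEL_HYPER] * config.n_hyper
    for idx, label in enumerate(labels):
        sig = _render_record(rng, config, label)
        if config.n_channels == 2:
            second = 0.6 * sig + config.noise_sd * rng.standard_normal(len(sig))
            channels = np.vstack([sig, second])
        else:
            channels = sig[None, :]
        records.append(
            BCGRecord(
                subject_id=f"S{idx:03d}",
                channels=channels,
                fs=config.fs,
                label=label,
                demographics={},
            )
        )
    return records


def generate_feature_table(config: SynthTableConfig) -> FeatureTable:
    """Balanced two-class Gaussian table with marked informative columns.

    Informative columns get a class-mean shift of ``effect_size`` (classes at
    -/+ effect_size/2); noise columns are class-independent standard normal.
    Column names (``inf_*`` / ``noise_*``) mark ground truth for test oracles.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n1 = n // 2
    labels = np.array([0] * (n - n1) + [1] * n1)
    d = config.d_informative + config.d_noise
    values = rng.standard_normal((n, d))
    shift = np.where(labels == 1, config.effect_size / 2.0, -config.effect_size / 2.0)
    values[:, : config.d_informative] += shift[:, None]
    names = [f"inf_{i}" for i in range(config.d_informative)] + [
        f"noise_{i}" for i in range(config.d_noise)
    ]
    return FeatureTable(
        values,
        names,
        labels,
        provenance={"source": "synthetic_table", "config": config.model_dump()},
    )


def write_cohort(records: list[BCGRecord], out_dir: str | Path) -> Path:
    """Write one waveform file per subject plus a manifest; returns manifest path.

    Waveforms are headerless delimited text, one sample per row (one or two
    columns). The manifest has columns
    ``subject_id,file,label,fs[,age,bmi,hr,sbp,dbp]``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    demo_keys = ["age", "bmi", "hr", "sbp", "dbp"]
    has_demo = any(any(k in r.demographics for k in demo_keys) for r in records)
    lines = ["subject_id,file,label,fs" + ("," + ",".join(demo_keys) if has_demo else "")]
    for rec in records:
        fname = f"{rec.subject_id}.csv"
        np.savetxt(out_dir / fname, rec.channels.T, fmt="%.6f", delimiter=",")
        row = f"{rec.subject_id},{fname},{LABEL_NAMES[rec.label]},{rec.fs:g}"
        if has_demo:
            row += "," + ",".join(
                f"{rec.demographics[k]:g}" if k in rec.demographics else "" for k in demo_keys
            )
        lines.append(row)
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
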