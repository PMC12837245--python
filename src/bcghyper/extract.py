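"""Segment-to-feature-vector extractors.

Two families:

* per-segment decompositions (K-means frame clustering, undecimated wavelet
  transform, empirical wavelet transform) that need no fitting across
  samples, and
* learned maps (PCA/kernel PCA, random feature mapping) that are fitted on a
  raw per-segment descriptor table from training data only and then applied
  to held-out segments.

Every extractor yields the same dimensionality for every segment and is
deterministic under a fixed seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pywt
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import KernelPCA
from sklearn.linear_model import Lasso

from .containers import FeatureTable, SegmentSet
from .ewt import ewt_decompose

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# small shared statistics


def _hjorth_mobility(x: np.ndarray) -> float:
    v = np.var(x)
    if v == 0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / v))


def _band_stats(band: np.ndarray, total_energy: float) -> list[float]:
    """(mean |.|, variance, energy fraction, skewness, kurtosis) of one band."""
    energy = float(np.sum(band**2))
    sd = band.std()
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(band))
        kurt = float(stats.kurtosis(band))
    frac = energy / total_energy if total_energy > 0 else 0.0
    return [float(np.mean(np.abs(band))), float(band.var()), frac, skew, kurt]


# ---------------------------------------------------------------------------
# K-means frame clustering


def squared_euclidean(p: np.ndarray, q: np.ndarray) -> float:
    """Squared Euclidean dissimilarity between two points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sum((p - q) ** 2))


def _frame_summaries(segment: np.ndarray, frame_len: int) -> np.ndarray:
    n_frames = len(segment) // frame_len
    frames = segment[: n_frames * frame_len].reshape(n_frames, frame_len)
    return np.column_stack([
        frames.mean(axis=1),
        frames.std(axis=1),
        np.mean(frames**2, axis=1),
        frames.max(axis=1) - frames.min(axis=1),
    ])


def kmeans_features(
    segments: SegmentSet, K: int = 4, frame_seconds: float = 2.0, seed: int = 0
) -> FeatureTable:
    """Cluster short-frame summaries of each segment with Lloyd's algorithm.

    Each segment is sliced into ``frame_seconds`` frames summarized by
    (mean, SD, energy, peak-to-peak); the K cluster centers (sorted by their
    energy coordinate for a deterministic order), cluster occupancy fractions
    and the final inertia form the segment's feature vector.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    frame_len = int(round(frame_seconds * segments.fs))
    n_frames = segments.segment_length // frame_len
    if n_frames < K:
        raise ValueError(f"segments yield {n_frames} frames, fewer than K={K}")

    rows = []
    for seg in segments.segments:
        pts = _frame_summaries(seg, frame_len)
        km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(pts)
        order = np.argsort(km.cluster_centers_[:, 2])  # by frame energy
        centers = km.cluster_centers_[order]
        occupancy = np.bincount(km.labels_, minlength=K)[order] / len(pts)
        rows.append(np.concatenate([centers.ravel(), occupancy, [km.inertia_]]))

    stat_names = ("mean", "sd", "energy", "p2p")
    names = [f"km_c{k}_{s}" for k in range(K) for s in stat_names]
    names += [f"km_occ{k}" for k in range(K)] + ["km_inertia"]
    return FeatureTable(
        np.asarray(rows), names, segments.labels.copy(),
        provenance={"extractor": "kmeans", "K": K, "frame_seconds": frame_seconds,
                    "seed": seed},
        subject_ids=list(segments.subject_ids),
    )


# ---------------------------------------------------------------------------
# undecimated (maximal-overlap) wavelet transform


def modwt(x: np.ndarray, wavelet: str = "db4", levels: int = 5) -> np.ndarray:
    """Undecimated wavelet bands ``[smooth, detail_levels, ..., detail_1]``.

    Every band has the length of the input (no down-sampling). Inputs whose
    length is not a multiple of ``2**levels`` are symmetrically padded and
    the coefficients trimmed back; energy conservation is then approximate
    near the edges only.
    """
    x = np.asarray(x, dtype=float)
    try:
        pywt.Wavelet(wavelet)
    except ValueError as exc:
        raise ValueError(f"unsupported wavelet name {wavelet!r}") from exc
    n = len(x)
    block = 2**levels
    pad = (-n) % block
    if pad:
        x = np.pad(x, (0, pad), mode="symmetric")
    coeffs = pywt.swt(x, wavelet, level=levels, trim_approx=True, norm=True)
    return np.vstack([c[:n] for c in coeffs])


def imodwt(bands: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Inverse of :func:`modwt` for inputs that needed no padding."""
    coeffs = [np.asarray(b, dtype=float) for b in bands]
    return pywt.iswt(coeffs, wavelet, norm=True)


def modwt_features(
    segments: SegmentSet, wavelet: str = "db4", levels: int = 5
) -> FeatureTable:
    """Per-band (mean |.|, variance, energy fraction, skewness, kurtosis)."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    rows = []
    for seg in segments.segments:
        bands = modwt(seg, wavelet, levels)
        total = float(np.sum(bands**2))
        row: list[float] = []
        for band in bands:
            row.extend(_band_stats(band, total))
        rows.append(row)
    band_names = [f"a{levels}"] + [f"d{j}" for j in range(levels, 0, -1)]
    stat_names = ("meanabs", "var", "efrac", "skew", "kurt")
    names = [f"modwt_{b}_{s}" for b in band_names for s in stat_names]
    return FeatureTable(
        np.asarray(rows), names, segments.labels.copy(),
        provenance={"extractor": "modwt", "wavelet": wavelet, "levels": levels},
        subject_ids=list(segments.subject_ids),
    )


# ---------------------------------------------------------------------------
# empirical wavelet transform


def ewt_features(segments: SegmentSet, n_modes: int = 5) -> FeatureTable:
    """Per-mode (energy fraction, spectral centroid, variance, Hjorth mobility).

    Segments whose spectra yield fewer maxima than requested fall back to
    fewer modes; the missing feature slots are zero-filled so the table keeps
    a fixed width.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    fs = segments.fs
    rows = []
    for seg in segments.segments:
        modes, _ = ewt_decompose(seg, fs, n_modes)
        total = float(np.sum(modes**2))
        row = np.zeros(4 * n_modes)
        for m, mode in enumerate(modes):
            mag = np.abs(np.fft.rfft(mode))
            freqs = np.fft.rfftfreq(len(mode), d=1.0 / fs)
            power = mag**2
            centroid = float(np.sum(freqs * power) / np.sum(power)) if power.sum() else 0.0
            energy = float(np.sum(mode**2))
            row[4 * m : 4 * m + 4] = [
                energy / total if total > 0 else 0.0,
                centroid,
                float(mode.var()),
                _hjorth_mobility(mode),
            ]
        rows.append(row)
    stat_names = ("efrac", "centroid", "var", "mobility")
    names = [f"ewt_m{m}_{s}" for m in range(n_modes) for s in stat_names]
    return FeatureTable(
        np.asarray(rows), names, segments.labels.copy(),
        provenance={"extractor": "ewt", "n_modes": n_modes},
        subject_ids=list(segments.subject_ids),
    )


# ---------------------------------------------------------------------------
# raw per-segment descriptors (input to the learned maps)

_SPECTRAL_BANDS = [(0.0, 0.5), (0.5, 2.0), (2.0, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, 50.0)]


def segment_descriptors(segments: SegmentSet) -> FeatureTable:
    """High-dimensional raw statistics per segment.

    Time-domain moments and quantiles, Hjorth parameters, fixed spectral-band
    energy fractions, spectral centroid, and an autocorrelation-based
    inter-beat-interval estimate (peak lag in the 0.4-1.5 s range). These are
    the inputs that PCA / kernel PCA / random feature mapping compress.
    """
    fs = segments.fs
    rows = []
    for seg in segments.segments:
        x = seg - seg.mean()
        sd = x.std()
        quants = np.quantile(seg, [0.1, 0.25, 0.5, 0.75, 0.9])
        mag2 = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
        total_p = mag2.sum()
        band_fracs = [
            float(mag2[(freqs >= lo) & (freqs < hi)].sum() / total_p) if total_p else 0.0
            for lo, hi in _SPECTRAL_BANDS
        ]
        centroid = float(np.sum(freqs * mag2) / total_p) if total_p else 0.0
        # autocorrelation IBI estimate (FFT-based, positive lags only)
        nlag = min(len(x) - 1, int(1.5 * fs))
        spec_full = np.abs(np.fft.rfft(x, n=2 * len(x))) ** 2
        ac = np.fft.irfft(spec_full)[: nlag + 1]
        ac = ac / ac[0] if ac[0] != 0 else ac
        lo = int(0.4 * fs)
        if nlag > lo:
            peak_lag = lo + int(np.argmax(ac[lo:]))
            ibi = peak_lag / fs
            ac_peak = float(ac[peak_lag])
        else:
            ibi, ac_peak = 0.0, 0.0
        mob = _hjorth_mobility(x)
        dx = np.diff(x)
        comp = _hjorth_mobility(dx) / mob if mob > 0 else 0.0
        rows.append(
            [seg.mean(), sd, float(stats.skew(x)) if sd else 0.0,
             float(stats.kurtosis(x)) if sd else 0.0,
             seg.max() - seg.min(), float(np.sqrt(np.mean(seg**2))),
             float(np.mean(np.abs(dx))), mob, comp, *quants, *band_fracs,
             centroid, ibi, ac_peak]
        )
    names = (
        ["t_mean", "t_sd", "t_skew", "t_kurt", "t_p2p", "t_rms", "t_madiff",
         "hjorth_mob", "hjorth_comp", "q10", "q25", "q50", "q75", "q90"]
        + [f"bandfrac_{lo:g}_{hi:g}" for lo, hi in _SPECTRAL_BANDS]
        + ["spec_centroid", "ibi_est", "ac_peak"]
    )
    return FeatureTable(
        np.asarray(rows), names, segments.labels.copy(),
        provenance={"extractor": "descriptors"},
        subject_ids=list(segments.subject_ids),
    )


# ---------------------------------------------------------------------------
# PCA / kernel PCA


@dataclass
class KPCAModel:
    """Fitted kernel principal component map (linear kernel = classical PCA)."""

    kernel: str
    n_components: int
    kernel_params: dict[str, Any]
    estimator: KernelPCA
    eigenvalues: np.ndarray

    def transform(self, table: FeatureTable) -> FeatureTable:
        proj = self.estimator.transform(table.values)
        names = [f"kpca_{self.kernel}_{i}" for i in range(proj.shape[1])]
        return FeatureTable(
            proj, names, table.labels.copy(),
            provenance={"extractor": "kpca", "kernel": self.kernel,
                        "n_components": self.n_components, **self.kernel_params},
            subject_ids=list(table.subject_ids) if table.subject_ids is not None else None,
        )


_KERNEL_ALIASES = {"linear": "linear", "gaussian": "rbf", "rbf": "rbf",
                   "polynomial": "poly", "poly": "poly"}


def pca_or_kpca_features(
    table: FeatureTable,
    kernel: str = "linear",
    n_components: int = 4,
    gamma: float | None = None,
    degree: int = 3,
) -> tuple[FeatureTable, KPCAModel]:
    """Kernel PCA on a descriptor table; linear kernel recovers classical PCA.

    The pairwise kernel matrix is double-centered and eigendecomposed;
    projections use the dual coefficients. Defaults: linear kernel, four
    components.
    """
    if kernel not in _KERNEL_ALIASES:
        raise ValueError(f"unsupported kernel {kernel!r}")
    max_comp = min(table.n_samples, table.n_features)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n, d)={max_comp}"
        )
    est = KernelPCA(
        n_components=n_components, kernel=_KERNEL_ALIASES[kernel],
        gamma=gamma, degree=degree, random_state=0,
    )
    proj = est.fit_transform(table.values)
    eig = est.eigenvalues_
    if np.any(eig < -1e-8 * max(1.0, float(eig.max(initial=0.0)))):
        raise np.linalg.LinAlgError("kernel matrix is not PSD beyond tolerance")
    model = KPCAModel(
        kernel=kernel, n_components=n_components,
        kernel_params={"gamma": gamma, "degree": degree},
        estimator=est, eigenvalues=eig,
    )
    names = [f"kpca_{kernel}_{i}" for i in range(proj.shape[1])]
    out = FeatureTable(
        proj, names, table.labels.copy(),
        provenance={"extractor": "kpca", "kernel": kernel, "n_components": n_components},
        subject_ids=list(table.subject_ids) if table.subject_ids is not None else None,
    )
    return out, model


# ---------------------------------------------------------------------------
# random feature mapping


@dataclass
class RFMModel:
    """Random ReLU feature groups with lasso-sparsified weights.

    Each of ``q`` groups draws a random linear map; a sparse autoencoding
    fine-tune (lasso from the inputs onto the group's random pre-activations)
    replaces the random weights with sparse ones before the ReLU.
    """

    q: int
    n_per_group: int
    gamma: float
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    def transform(self, table: FeatureTable) -> FeatureTable:
        groups = [
            np.maximum(table.values @ W + b, 0.0)
            for W, b in zip(self.weights, self.biases)
        ]
        values = np.hstack(groups)
        names = [f"rfm_g{g}_n{j}" for g in range(self.q) for j in range(self.n_per_group)]
        return FeatureTable(
            values, names, table.labels.copy(),
            provenance={"extractor": "rfm", "q": self.q,
                        "n_per_group": self.n_per_group, "gamma": self.gamma},
            subject_ids=list(table.subject_ids) if table.subject_ids is not None else None,
        )


def sparse_finetune(G: np.ndarray, target: np.ndarray, gamma: float) -> np.ndarray:
    """Solve ``argmin_W ||G W - target||^2 + gamma ||W||_1``.

    ``gamma = 0`` reduces to ordinary least squares; large ``gamma`` shrinks
    the weights to zero (lasso coordinate descent otherwise).
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if gamma == 0:
        W, *_ = np.linalg.lstsq(G, target, rcond=None)
        return W
    lasso = Lasso(alpha=gamma, fit_intercept=False, max_iter=5000)
    lasso.fit(G, target)
    return np.asarray(lasso.coef_).T.reshape(G.shape[1], -1)


def rfm_features(
    table: FeatureTable,
    q: int = 10,
    n_per_group: int = 8,
    gamma: float = 0.01,
    seed: int = 0,
) -> tuple[FeatureTable, RFMModel]:
    """Fit the random feature mapping on a (standardized) descriptor table."""
    rng = np.random.default_rng(seed)
    model = RFMModel(q=q, n_per_group=n_per_group, gamma=gamma)
    G = table.values
    for _ in range(q):
        W0 = rng.standard_normal((table.n_features, n_per_group))
        b = rng.standard_normal(n_per_group)
        pre = G @ W0 + b
        W = sparse_finetune(G, pre, gamma)
        model.weights.append(W)
        model.biases.append(b)
    return model.transform(table), model
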