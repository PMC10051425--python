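"""Handcrafted statistical / temporal / spectral features and normalization.

The handcrafted view of a window is computed per tri-axial sensor over the
four channels x, y, z and the Euclidean magnitude: arithmetic mean, standard
deviation, skewness E(s-s_bar)^3/sigma^3, kurtosis E(s-s_bar)^4/(E(s-s_bar)^2)^2
(raw fourth standardized moment, not excess), spectral energy of configurable
frequency-index bands (1/(b-a+1)) * sum_{i=a}^{b} |S_i|^2 on the real FFT,
plus per-sensor signal magnitude area (1/3) * sum_axes sum_t |s| and the three
pairwise Pearson correlations between axes.  Auxiliary scalars (speed, phone
state flags) pass through unchanged.

Conventions for degenerate inputs: a constant channel has sd = 0 and, by
convention, skewness = kurtosis = 0 and correlation 0 with any channel.
All moments use the population (divide-by-N) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import DomainDataset
from .synthetic import AUX_NAMES

DEFAULT_BANDS: tuple[tuple[int, int], ...] = ((1, 5), (6, 15), (16, 40))


def default_bands(window_samples: int) -> tuple[tuple[int, int], ...]:
    """Default spectral bands for a window of T samples.

    The reference bands target the 250-sample default window (low / gait /
    high-frequency content); shorter or longer windows get the same bands
    scaled proportionally, kept disjoint and within the rFFT range.
    """
    n_bins = window_samples // 2 + 1
    scale = window_samples / 250.0
    bands: list[tuple[int, int]] = []
    prev_end = 0
    for a, b in DEFAULT_BANDS:
        lo = max(prev_end + 1, round(a * scale))
        hi = min(max(lo, round(b * scale)), n_bins - 1)
        if lo > n_bins - 1:
            break
        bands.append((lo, hi))
        prev_end = hi
    if not bands:
        raise ValueError(f"window of {window_samples} samples is too short for "
                         "spectral bands")
    return tuple(bands)


SENSOR_NAMES = ("acc", "gyro", "mag")
CHANNEL_NAMES = ("x", "y", "z", "norm")
_EPS = 1e-8


@dataclass
class FeatureVector:
    values: np.ndarray
    feature_names: list[str]


@dataclass
class NormalizationStats:
    mean: np.ndarray
    sd: np.ndarray


def _validate_bands(bands, n_bins: int) -> list[tuple[int, int]]:
    out = []
    for band in bands:
        a, b = int(band[0]), int(band[1])
        if not (0 <= a <= b < n_bins):
            raise ValueError(f"band [{a}, {b}] outside valid FFT index range [0, {n_bins - 1}]")
        out.append((a, b))
    return out


def feature_names(bands=DEFAULT_BANDS, aux_names=AUX_NAMES) -> list[str]:
    names: list[str] = []
    for sensor in SENSOR_NAMES:
        for ch in CHANNEL_NAMES:
            names += [f"{sensor}_{ch}_{stat}" for stat in ("mean", "sd", "skew", "kurt")]
            names += [f"{sensor}_{ch}_energy_{a}_{b}" for a, b in bands]
        names.append(f"{sensor}_sma")
        names += [f"{sensor}_corr_{p}" for p in ("xy", "xz", "yz")]
    names += list(aux_names)
    return names


def handcrafted_features_batch(raw: np.ndarray, aux: np.ndarray | None = None,
                               bands=None) -> np.ndarray:
    """Vectorized featurization of raw windows [N, 3, 3, T] -> [N, F]."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 4 or raw.shape[1:3] != (3, 3):
        raise ValueError("raw must have shape [N, 3, 3, T]")
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw window contains NaN or infinite values")
    N, _, _, T = raw.shape
    n_bins = T // 2 + 1
    bands = _validate_bands(default_bands(T) if bands is None else bands, n_bins)

    norm = np.sqrt((raw ** 2).sum(axis=2, keepdims=True))        # [N,3,1,T]
    chans = np.concatenate([raw, norm], axis=2)                  # [N,3,4,T]

    mean = chans.mean(axis=-1)
    centered = chans - mean[..., None]
    m2 = (centered ** 2).mean(axis=-1)
    m3 = (centered ** 3).mean(axis=-1)
    m4 = (centered ** 4).mean(axis=-1)
    sd = np.sqrt(m2)
    nz = m2 > 0
    skew = np.zeros_like(m3)
    kurt = np.zeros_like(m4)
    np.divide(m3, sd ** 3, out=skew, where=nz)
    np.divide(m4, m2 ** 2, out=kurt, where=nz)

    spec = np.abs(np.fft.rfft(chans, axis=-1)) ** 2              # [N,3,4,n_bins]
    energies = np.stack(
        [spec[..., a:b + 1].sum(axis=-1) / (b - a + 1) for a, b in bands], axis=-1)

    sma = np.abs(raw).sum(axis=(2, 3)) / 3.0                     # [N,3]

    pairs = ((0, 1), (0, 2), (1, 2))
    corr = np.zeros((N, 3, 3))
    for k, (i, j) in enumerate(pairs):
        cov = (centered[:, :, i] * centered[:, :, j]).mean(axis=-1)
        denom = sd[:, :, i] * sd[:, :, j]
        np.divide(cov, denom, out=corr[:, :, k], where=denom > 0)

    per_channel = np.concatenate(
        [mean[..., None], sd[..., None], skew[..., None], kurt[..., None], energies],
        axis=-1)                                                 # [N,3,4,4+B]
    per_sensor = np.concatenate(
        [per_channel.reshape(N, 3, -1), sma[..., None], corr], axis=-1)  # [N,3,*]
    feats = per_sensor.reshape(N, -1)
    if aux is not None:
        feats = np.concatenate([feats, np.asarray(aux, dtype=np.float64)], axis=1)
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite feature value produced")
    return feats


def handcrafted_features(window: np.ndarray, aux: np.ndarray | None = None,
                         bands=None) -> FeatureVector:
    """Featurize a single window [3, 3, T] (plus optional aux scalars)."""
    window = np.asarray(window, dtype=np.float64)
    if bands is None:
        bands = default_bands(window.shape[-1])
    aux_arr = None if aux is None else np.asarray(aux, dtype=np.float64)[None, :]
    values = handcrafted_features_batch(window[None], aux_arr, bands)[0]
    aux_names = [] if aux is None else (
        list(AUX_NAMES) if len(aux_arr[0]) == len(AUX_NAMES)
        else [f"aux_{i}" for i in range(len(aux_arr[0]))])
    return FeatureVector(values=values, feature_names=feature_names(bands, aux_names))


def zscore_fit(features) -> NormalizationStats:
    """Per-feature mean and population standard deviation of the fitting set."""
    X = _as_matrix(features)
    if X.shape[0] < 2:
        raise ValueError("zscore_fit needs at least two feature vectors")
    return NormalizationStats(mean=X.mean(axis=0), sd=X.std(axis=0))


def zscore_apply(features, stats: NormalizationStats):
    """(x - mean) / max(sd, eps); accepts one vector or a matrix."""
    single = isinstance(features, FeatureVector)
    X = features.values if single else np.asarray(features, dtype=np.float64)
    if X.shape[-1] != stats.mean.shape[0]:
        raise ValueError(f"feature length {X.shape[-1]} does not match stats "
                         f"length {stats.mean.shape[0]}")
    Z = (X - stats.mean) / np.maximum(stats.sd, _EPS)
    if single:
        return FeatureVector(values=Z, feature_names=features.feature_names)
    return Z


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = features
    else:
        rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f)
                for f in features]
        if not rows:
            raise ValueError("empty feature list")
        X = np.stack(rows)
    return np.asarray(X, dtype=np.float64)


def featurize_dataset(dataset: DomainDataset, bands=None) -> DomainDataset:
    """Attach the handcrafted feature matrix to a dataset (in place) and return it."""
    if bands is None:
        bands = default_bands(dataset.raw.shape[-1])
    dataset.features = handcrafted_features_batch(dataset.raw, dataset.aux, bands)
    dataset.feature_names = feature_names(bands)
    return dataset
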