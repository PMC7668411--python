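"""Wavelet band decomposition and band-power (RMS) feature extraction.

Each 1-s, 1 kHz channel signal is decomposed with a 7-level Daubechies-4
(db4) discrete wavelet transform. The two finest detail levels (d1: 250-500
Hz, d2: 125-250 Hz) are discarded as noise; d3..d7 and the approximation a7
are each reconstructed alone back to the original sampling rate, yielding
six band-limited signals mapped onto the canonical neural oscillation bands:

    d3 -> high-gamma (61-125 Hz)   d6 -> alpha (8-16 Hz)
    d4 -> gamma      (31-59 Hz)    d7 -> theta (4-8 Hz)
    d5 -> beta       (16-30 Hz)    a7 -> delta (0.03-4 Hz)

The dyadic cut-offs at 1 kHz (62.5, 31.25, 15.6, 7.8, 3.9 Hz) are the
operative edges; the band names carry the nominal ranges. One RMS value per
band per sensor gives a trials x (n_sensors * 6) feature matrix — 1176
columns for the full 196-gradiometer array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .preprocess import EpochSet

__all__ = [
    "BANDS",
    "BAND_SOURCES",
    "FeatureMatrix",
    "wavelet_bands",
    "rms",
    "extract_features",
    "subset_features",
]

#: Fixed band order used for column layout (band-minor within each sensor).
BANDS: tuple[str, ...] = ("high_gamma", "gamma", "beta", "alpha", "theta", "delta")

#: Wavelet coefficient feeding each band at 1 kHz with a 7-level db4 DWT.
BAND_SOURCES: dict[str, str] = {
    "high_gamma": "d3",
    "gamma": "d4",
    "beta": "d5",
    "alpha": "d6",
    "theta": "d7",
    "delta": "a7",
}

_WAVELET = "db4"
_LEVELS = 7
_DWT_MODE = "symmetric"


@dataclass
class FeatureMatrix:
    """Trials x features RMS band-power matrix with a (sensor, band) column map."""

    values: np.ndarray
    labels: np.ndarray
    sensor_ids: list[str]
    bands: tuple[str, ...] = BANDS
    column_index: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.labels = np.asarray(self.labels)
        if not self.column_index:
            self.column_index = {
                (s, b): i * len(self.bands) + j
                for i, s in enumerate(self.sensor_ids)
                for j, b in enumerate(self.bands)
            }
        if self.values.shape[1] != len(self.sensor_ids) * len(self.bands):
            raise ValueError("column count must equal n_sensors * n_bands")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must equal number of trials")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        inv = {v: k for k, v in self.column_index.items()}
        return [f"{inv[i][0]}_{inv[i][1]}" for i in range(self.n_features)]


def wavelet_bands(
    x: np.ndarray, wavelet: str = _WAVELET, levels: int = _LEVELS
) -> np.ndarray:
    """Decompose signal(s) into the six band reconstructions.

    ``x`` may be 1-D or N-D (transform along the last axis). Returns an array
    of shape ``(6,) + x.shape`` in :data:`BANDS` order, each entry the inverse
    DWT of a single coefficient level (others zeroed), truncated to the input
    length. By linearity, the six bands plus the discarded d1/d2
    reconstructions sum exactly to the input.
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.empty((len(BANDS),) + x.shape)
    for bi, rec in enumerate(_iter_band_reconstructions(x, wavelet, levels)):
        out[bi] = rec
    return out


def _iter_band_reconstructions(x: np.ndarray, wavelet: str, levels: int):
    """Yield the six single-level reconstructions in :data:`BANDS` order."""
    if x.shape[-1] < 2**levels:
        raise ValueError(f"signal length {x.shape[-1]} too short for {levels} levels")
    coeffs = pywt.wavedec(x, wavelet, mode=_DWT_MODE, level=levels, axis=-1)
    # coeffs = [a7, d7, d6, ..., d1]
    source_pos = {"a7": 0}
    for lv in range(1, levels + 1):
        source_pos[f"d{lv}"] = levels + 1 - lv
    for band in BANDS:
        pos = source_pos[BAND_SOURCES[band]]
        solo = [c if i == pos else np.zeros_like(c) for i, c in enumerate(coeffs)]
        rec = pywt.waverec(solo, wavelet, mode=_DWT_MODE, axis=-1)
        yield rec[..., : x.shape[-1]]


def rms(window: np.ndarray) -> float:
    """Root mean square, ``sqrt(mean(x**2))``, of a non-empty 1-D window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValueError("window must be non-empty")
    return float(np.sqrt(np.mean(window**2)))


def extract_features(epochs: EpochSet) -> FeatureMatrix:
    """Per-trial, per-sensor, per-band RMS features for a 1-s window at 1 kHz.

    Columns are sensor-major, band-minor: sensor i occupies columns
    ``6*i .. 6*i+5`` in :data:`BANDS` order.
    """
    if not np.isclose(epochs.fs, 1000.0):
        raise ValueError("feature extraction expects 1 kHz epochs (resample first)")
    x = epochs.data.astype(np.float64)
    band_rms = np.empty((len(BANDS), epochs.n_trials, epochs.n_channels))
    for bi, rec in enumerate(_iter_band_reconstructions(x, _WAVELET, _LEVELS)):
        band_rms[bi] = np.sqrt(np.mean(rec**2, axis=-1))
    # -> (trials, channels, 6) -> (trials, channels*6)
    values = np.transpose(band_rms, (1, 2, 0)).reshape(epochs.n_trials, -1)
    return FeatureMatrix(values, epochs.labels.copy(), list(epochs.channel_ids))


def subset_features(features: FeatureMatrix, sensors: list[str]) -> FeatureMatrix:
    """Keep the six band columns of each requested sensor (given order)."""
    unknown = [s for s in sensors if s not in features.sensor_ids]
    if unknown:
        raise ValueError(f"unknown sensor id(s): {unknown}")
    cols = [features.column_index[(s, b)] for s in sensors for b in features.bands]
    return FeatureMatrix(
        features.values[:, cols].copy(),
        features.labels.copy(),
        list(sensors),
        features.bands,
    )
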