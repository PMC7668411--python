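"""Signal conditioning for multichannel MEG epochs.

The chain mirrors a standard Neuromag gradiometer workflow: zero-phase
Butterworth low-pass below 250 Hz, 60 Hz notch (plus harmonics), resampling
to 1 kHz, automated flat/noisy channel rejection, amplitude-based trial
rejection, trial balancing to a fixed count per class, and extraction of the
1-s analysis windows (covert "imagination" at 1–2 s and overt "production"
at 2–3 s after stimulus onset).

Operations never mutate their input; each returns a new :class:`EpochSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "RejectionReport",
    "lowpass",
    "notch",
    "resample",
    "reject_channels",
    "reject_trials",
    "balance_trials",
    "extract_window",
    "STAGE_WINDOWS",
]

#: Analysis windows in seconds relative to stimulus onset, [start, stop).
#: The covert (imagination) second follows the 1-s stimulus; articulation is
#: cued at 2 s and the first second after the cue is analysed.
STAGE_WINDOWS: dict[str, tuple[float, float]] = {
    "imagination": (1.0, 2.0),
    "production": (2.0, 3.0),
}


@dataclass
class EpochSet:
    """Trials x channels x samples epoch container.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_samples)``; nominal units
        are magnetic field gradient (T/m), but the pipeline is unit-agnostic.
    fs
        Sampling rate in Hz.
    labels
        Integer class id per trial, shape ``(n_trials,)``.
    channel_ids
        One Neuromag-style name per channel (e.g. ``"MEG0432"``).
    t0
        Time of the first sample in seconds relative to stimulus onset
        (negative for a pre-stimulus baseline).
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_ids: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError("channel_ids length must equal number of channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.fs, self.labels.copy(), list(self.channel_ids), self.t0
        )

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


@dataclass
class RejectionReport:
    """Record of channels/trials discarded by the automated rejection steps."""

    dropped_channels: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    dropped_trials: list[tuple[int, str]] = field(default_factory=list)  # (index, reason)
    retained_counts: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dropped_channels": [list(t) for t in self.dropped_channels],
            "dropped_trials": [list(t) for t in self.dropped_trials],
            "retained_counts": {str(k): v for k, v in self.retained_counts.items()},
        }


def _apply_sos(epochs: EpochSet, sos: np.ndarray) -> EpochSet:
    out = epochs.copy()
    # sosfiltfilt broadcasts over leading axes: one pass for all trials/channels
    out.data = signal.sosfiltfilt(sos, epochs.data.astype(np.float64), axis=-1).astype(
        epochs.data.dtype
    )
    return out


def lowpass(epochs: EpochSet, cutoff: float = 250.0, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth low-pass, applied forward-backward per signal."""
    if cutoff >= epochs.fs / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({epochs.fs / 2} Hz)"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=epochs.fs, output="sos")
    return _apply_sos(epochs, sos)


def notch(epochs: EpochSet, base: float = 60.0, n_harmonics: int = 4, q: float = 30.0) -> EpochSet:
    """Remove line noise at ``base`` Hz and its harmonics with narrow IIR notches.

    Harmonics are applied at base, 2*base, ... up to ``n_harmonics * base``,
    silently stopping below the Nyquist frequency.
    """
    if base <= 0:
        raise ValueError("base frequency must be positive")
    out = epochs.copy()
    x = out.data.astype(np.float64)
    for k in range(1, n_harmonics + 1):
        f = base * k
        if f >= epochs.fs / 2:
            break
        b, a = signal.iirnotch(f, q, fs=epochs.fs)
        # long padding: narrow notches ring, and the default padlen (~9
        # samples) leaves visible edge transients on multi-second epochs
        padlen = min(x.shape[-1] - 1, int(epochs.fs))
        x = signal.filtfilt(b, a, x, axis=-1, padlen=padlen)
    out.data = x.astype(epochs.data.dtype)
    return out


def resample(epochs: EpochSet, target_fs: float = 1000.0) -> EpochSet:
    """Downsample to ``target_fs`` (polyphase); upsampling is refused.

    Output length is ``round(n_samples * target_fs / fs)``. Anti-aliasing is
    provided both by the polyphase filter and by the low-pass normally applied
    earlier in the chain.
    """
    if target_fs > epochs.fs:
        raise ValueError("upsampling is not supported (target_fs > fs)")
    if target_fs == epochs.fs:
        return epochs.copy()
    frac = Fraction(target_fs / epochs.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out_len = int(round(epochs.n_samples * target_fs / epochs.fs))
    data = signal.resample_poly(epochs.data.astype(np.float64), up, down, axis=-1)
    data = data[..., :out_len]
    out = epochs.copy()
    out.data = data.astype(epochs.data.dtype)
    out.fs = float(target_fs)
    return out


def reject_channels(
    epochs: EpochSet, flat_eps: float = 1e-6, noisy_z: float = 5.0
) -> tuple[EpochSet, RejectionReport]:
    """Drop flat (std < ``flat_eps``) and overly noisy channels.

    A channel is "noisy" when the z-score of its log-variance, computed across
    the non-flat channels, exceeds ``noisy_z``. Defaults are calibrated so
    clean output of the synthetic generator loses no channels.
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    std = epochs.data.astype(np.float64).std(axis=(0, 2))
    flat = std < flat_eps
    reasons: dict[int, str] = {i: "flat" for i in np.flatnonzero(flat)}
    ok = ~flat
    if ok.sum() >= 2:
        logvar = np.log(std[ok] ** 2)
        z = (logvar - logvar.mean()) / (logvar.std() + 1e-300)
        for idx, zi in zip(np.flatnonzero(ok), z):
            if zi > noisy_z:
                reasons[int(idx)] = "noisy"
    keep = np.array([i not in reasons for i in range(epochs.n_channels)])
    if not keep.any():
        raise RuntimeError("all channels rejected")
    report = RejectionReport(
        dropped_channels=[(epochs.channel_ids[i], r) for i, r in sorted(reasons.items())],
        retained_counts=epochs.class_counts(),
    )
    out = EpochSet(
        epochs.data[:, keep, :].copy(),
        epochs.fs,
        epochs.labels.copy(),
        [c for c, k in zip(epochs.channel_ids, keep) if k],
        epochs.t0,
    )
    return out, report


def reject_trials(
    epochs: EpochSet, peak_thresh: float | None = None, blink_band_hz: float = 4.0
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials whose blink-band peak exceeds ``peak_thresh`` on any channel.

    This automated criterion replaces manual visual inspection: ocular and
    movement artifacts are large slow transients, so the peak is measured on
    the < ``blink_band_hz`` zero-phase-filtered signal, where task-band
    oscillations contribute almost nothing. When ``peak_thresh`` is None it
    defaults to 8x the median channel standard deviation — blink-like
    transients (>= 10 sd) are caught while clean background (whose slow-band
    content is a small fraction of the total) survives by a wide margin.
    """
    if peak_thresh is None:
        peak_thresh = 8.0 * float(
            np.median(epochs.data.astype(np.float64).std(axis=(0, 2)))
        )
    if not peak_thresh > 0:
        raise ValueError("peak_thresh must be positive")
    sos = signal.butter(4, blink_band_hz, btype="low", fs=epochs.fs, output="sos")
    slow = signal.sosfiltfilt(sos, epochs.data.astype(np.float64), axis=-1)
    peaks = np.abs(slow).max(axis=(1, 2))
    bad = peaks > peak_thresh
    keep = ~bad
    retained_labels = epochs.labels[keep]
    for cls in np.unique(epochs.labels):
        if not np.any(retained_labels == cls):
            raise RuntimeError(f"trial rejection left class {cls} with 0 trials")
    report = RejectionReport(
        dropped_trials=[(int(i), "peak") for i in np.flatnonzero(bad)],
        retained_counts={
            int(v): int(c) for v, c in zip(*np.unique(retained_labels, return_counts=True))
        },
    )
    out = EpochSet(
        epochs.data[keep].copy(), epochs.fs, retained_labels.copy(),
        list(epochs.channel_ids), epochs.t0,
    )
    return out, report


def balance_trials(epochs: EpochSet, n_per_class: int = 60) -> EpochSet:
    """Keep the first ``n_per_class`` trials (acquisition order) of each class."""
    keep = np.zeros(epochs.n_trials, dtype=bool)
    for cls in np.unique(epochs.labels):
        idx = np.flatnonzero(epochs.labels == cls)
        if len(idx) < n_per_class:
            raise RuntimeError(
                f"class {cls} has only {len(idx)} trials (< {n_per_class})"
            )
        keep[idx[:n_per_class]] = True
    return EpochSet(
        epochs.data[keep].copy(), epochs.fs, epochs.labels[keep].copy(),
        list(epochs.channel_ids), epochs.t0,
    )


def extract_window(epochs: EpochSet, stage: str) -> EpochSet:
    """Extract the 1-s analysis window for ``stage`` ("imagination"/"production")."""
    if stage not in STAGE_WINDOWS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(STAGE_WINDOWS)}")
    start, stop = STAGE_WINDOWS[stage]
    i0 = int(round((start - epochs.t0) * epochs.fs))
    i1 = int(round((stop - epochs.t0) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_samples:
        raise ValueError(
            f"window [{start}, {stop}) s outside epoch span "
            f"[{epochs.t0}, {epochs.t0 + epochs.n_samples / epochs.fs}) s"
        )
    return EpochSet(
        epochs.data[:, :, i0:i1].copy(), epochs.fs, epochs.labels.copy(),
        list(epochs.channel_ids), start,
    )
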