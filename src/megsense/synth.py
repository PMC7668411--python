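"""Synthetic neuromagnetic epoch generator with planted ground truth.

Real MEG speech-decoding datasets are rarely shareable, so every downstream
stage here is exercised on simulated gradiometer epochs whose informative
sensors and frequency bands are known exactly. A trial is broadband
background noise plus, for its class, band-limited oscillatory bursts added
on that class's planted sensors inside the imagination (1-2 s) and
production (2-3 s) windows. Band power — not phase — carries the class
information, matching the RMS band-power features used downstream.

The defaults emulate the acquisition geometry of a 5-phrase overt/covert
speech protocol: 196 gradiometers, 60 trials per phrase, epochs from -0.5 to
5 s around stimulus onset at a 4 kHz raw rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import EpochSet, STAGE_WINDOWS

__all__ = [
    "SensorLayout",
    "SimulationConfig",
    "GroundTruth",
    "BAND_EDGES",
    "make_layout",
    "default_planted_map",
    "simulate_epochs",
    "inject_artifacts",
]

#: Nominal frequency edges (Hz) of the six canonical bands, high to low.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "high_gamma": (61.0, 125.0),
    "gamma": (31.0, 59.0),
    "beta": (16.0, 30.0),
    "alpha": (8.0, 16.0),
    "theta": (4.0, 8.0),
    "delta": (0.03, 4.0),
}


@dataclass
class SensorLayout:
    """Per-channel geometry: 3-D position (cm, head coordinates) and hemisphere.

    The lateral axis is x; by convention x < 0 is the left hemisphere.
    """

    channel_ids: list[str]
    positions: np.ndarray  # (n, 3) cm
    hemispheres: list[str]  # "left" | "right"
    channel_type: str = "gradiometer"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if self.positions.shape != (len(self.channel_ids), 3):
            raise ValueError("positions must be (n_channels, 3)")
        for x, h in zip(self.positions[:, 0], self.hemispheres):
            if (x < 0) != (h == "left"):
                raise ValueError("hemisphere tag inconsistent with lateral coordinate sign")

    @property
    def n_sensors(self) -> int:
        return len(self.channel_ids)

    def side(self, hemisphere: str) -> list[str]:
        """Channel ids of one hemisphere, in layout order."""
        if hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        return [c for c, h in zip(self.channel_ids, self.hemispheres) if h == hemisphere]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults mirror the emulated protocol."""

    n_sensors: int = 196
    n_classes: int = 5
    n_trials_per_class: int = 60
    fs_raw: float = 4000.0
    epoch_window: tuple[float, float] = (-0.5, 5.0)
    #: class id -> list of (sensor index, band name, effect RMS amplitude)
    planted_map: dict[int, list[tuple[int, str, float]]] | None = None
    noise_sd: float = 1.0
    #: sd (log scale) of the log-normal per-burst amplitude jitter emulating
    #: trial-to-trial cortical power variability; 0 disables it
    amplitude_jitter: float = 0.25
    background_spectrum: str = "white"  # or "one_over_f"
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_map is None:
            self.planted_map = default_planted_map(
                self.n_classes, self.n_sensors
            )
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")
        for cls, effects in self.planted_map.items():
            for sensor, band, amp in effects:
                if amp < 0:
                    raise ValueError("effect amplitudes must be >= 0")
                if not 0 <= sensor < self.n_sensors:
                    raise ValueError(f"planted sensor index {sensor} out of range")
                if band not in BAND_EDGES:
                    raise ValueError(
                        f"unknown band {band!r}; expected one of {sorted(BAND_EDGES)}"
                    )


@dataclass
class GroundTruth:
    """What the generator planted — the key for recovery tests."""

    informative_sensors: dict[int, set[int]] = field(default_factory=dict)
    informative_bands: dict[int, set[str]] = field(default_factory=dict)
    artifact_trials: set[int] = field(default_factory=set)
    flat_channels: set[int] = field(default_factory=set)

    @property
    def all_informative_sensors(self) -> set[int]:
        out: set[int] = set()
        for s in self.informative_sensors.values():
            out |= s
        return out


def default_planted_map(
    n_classes: int = 5,
    n_sensors: int = 196,
    n_informative: int = 9,
    amplitude: float = 2.0,
) -> dict[int, list[tuple[int, str, float]]]:
    """Distributed class signatures over ``n_informative`` evenly spaced sensors.

    Each informative sensor oscillates in one fixed band (rotating through
    the six bands) for every class, but at a class-dependent amplitude level
    cycling through 0.5x..1x the nominal ``amplitude``. Because short
    band-limited bursts have large natural power variability, one sensor's
    graded levels overlap between classes and carry only weak information;
    accuracy accumulates as sensors with complementary level patterns are
    combined — the way distributed cortical band-power patterns behave.
    The nominal amplitude defaults to 2x the unit background noise sd.

    Planted bands rotate through the five bands at or above theta; delta is
    left to background and blink-like artifacts, mirroring where task-band
    speech-decoding effects and ocular artifacts respectively live.
    """
    bands = [b for b in BAND_EDGES if b != "delta"]
    informative = np.unique(
        np.linspace(0, n_sensors - 1, n_informative).round().astype(int)
    )
    mapping: dict[int, list[tuple[int, str, float]]] = {}
    for k in range(n_classes):
        mapping[k] = [
            (
                int(informative[j]),
                bands[j % len(bands)],
                amplitude * (0.5 + 0.5 * ((j + k) % n_classes) / max(n_classes - 1, 1)),
            )
            for j in range(len(informative))
        ]
    return mapping


def make_layout(n_sensors: int, seed: int) -> SensorLayout:
    """Place ``n_sensors`` gradiometers on an upper hemispherical shell (r = 10 cm).

    Left and right hemispheres get exactly ``n_sensors / 2`` sensors each:
    left-side points are drawn at random on the shell and mirrored across the
    x = 0 plane, with left/right channels interleaved in index order.
    """
    if n_sensors < 2 or n_sensors % 2:
        raise ValueError("n_sensors must be an even count >= 2")
    rng = np.random.default_rng(seed)
    half = n_sensors // 2
    # azimuth kept away from the midline so the lateral sign is unambiguous
    phi = rng.uniform(np.pi / 2 + 0.05, 3 * np.pi / 2 - 0.05, half)
    theta = np.arccos(rng.uniform(0.05, 0.95, half))  # polar angle from z-axis
    r = 10.0
    left = np.column_stack(
        [r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi), r * np.cos(theta)]
    )
    right = left * np.array([-1.0, 1.0, 1.0])
    positions = np.empty((n_sensors, 3))
    positions[0::2] = left
    positions[1::2] = right
    hemispheres = ["left", "right"] * half
    channel_ids = [f"MEG{10 * (i + 1) + 2:04d}" for i in range(n_sensors)]
    return SensorLayout(channel_ids, positions, hemispheres)


_BAND_SIGMA_CACHE: dict[tuple[float, float, float], float] = {}


def _band_process_sd(fs: float, lo: float, hi: float) -> float:
    """Steady-state sd of unit white noise through the band-pass (cached)."""
    key = (fs, lo, hi)
    if key not in _BAND_SIGMA_CACHE:
        sos = signal.butter(4, (lo, hi), btype="band", fs=fs, output="sos")
        x = signal.sosfilt(sos, np.random.default_rng(12345).standard_normal(int(60 * fs)))
        _BAND_SIGMA_CACHE[key] = float(x[int(5 * fs):].std())
    return _BAND_SIGMA_CACHE[key]


def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float
) -> np.ndarray:
    """Gaussian noise band-passed with a 4th-order Butterworth, RMS ``rms``.

    Scaled to the target RMS in expectation (via the steady-state process
    sd), not per realisation — the natural trial-to-trial band-power
    variability of a short burst (large for narrow bands) is preserved,
    as in real oscillatory activity.
    """
    lo = max(band[0], 0.5)  # sub-0.5 Hz is unresolvable inside a 1-s burst
    hi = min(band[1], 0.99 * fs / 2)
    sos = signal.butter(4, (lo, hi), btype="band", fs=fs, output="sos")
    # pad so filter transients settle outside the returned burst
    pad = int(fs)
    x = signal.sosfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    return x * (rms / _band_process_sd(fs, lo, hi))


def _one_over_f_noise(rng: np.random.Generator, shape: tuple, fs: float, sd: float) -> np.ndarray:
    """Background with 1/f amplitude spectrum, unit-variance scaled to ``sd``."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1 / fs)
    scale = 1.0 / np.maximum(f, f[1] if n > 1 else 1.0)
    spec *= scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    x *= sd / x.std(axis=-1, keepdims=True)
    return x


def simulate_epochs(
    config: SimulationConfig, layout: SensorLayout
) -> tuple[EpochSet, GroundTruth]:
    """Generate an epoch set with planted class-specific band power.

    Bursts are added inside both task windows (imagination 1-2 s, production
    2-3 s) on the planted sensors of each trial's class; background noise is
    white (or 1/f) Gaussian everywhere. Deterministic given ``config.seed``.
    """
    if layout.n_sensors != config.n_sensors:
        raise ValueError("layout size does not match config.n_sensors")
    rng = np.random.default_rng(config.seed)
    t0, t1 = config.epoch_window
    n_samples = int(round((t1 - t0) * config.fs_raw))
    n_trials = config.n_classes * config.n_trials_per_class
    labels = np.tile(np.arange(config.n_classes), config.n_trials_per_class)

    if config.background_spectrum == "white":
        data = rng.standard_normal((n_trials, config.n_sensors, n_samples)).astype(np.float32)
        data *= np.float32(config.noise_sd)
    elif config.background_spectrum == "one_over_f":
        data = np.empty((n_trials, config.n_sensors, n_samples), dtype=np.float32)
        for tr in range(n_trials):
            data[tr] = _one_over_f_noise(
                rng, (config.n_sensors, n_samples), config.fs_raw, config.noise_sd
            )
    else:
        raise ValueError("background_spectrum must be 'white' or 'one_over_f'")

    windows = []
    for start, stop in STAGE_WINDOWS.values():
        i0 = int(round((start - t0) * config.fs_raw))
        i1 = int(round((stop - t0) * config.fs_raw))
        windows.append((i0, i1))

    truth = GroundTruth()
    for cls, effects in config.planted_map.items():
        truth.informative_sensors[cls] = {s for s, _, a in effects if a > 0}
        truth.informative_bands[cls] = {b for _, b, a in effects if a > 0}

    for tr in range(n_trials):
        cls = int(labels[tr])
        for sensor, band, amp in config.planted_map.get(cls, []):
            if amp <= 0:
                continue
            for i0, i1 in windows:
                if config.amplitude_jitter > 0:
                    # median-preserving log-normal trial-to-trial power jitter
                    amp_t = amp * rng.lognormal(0.0, config.amplitude_jitter)
                else:
                    amp_t = amp
                burst = _band_limited_noise(
                    rng, i1 - i0, config.fs_raw, BAND_EDGES[band], amp_t
                )
                data[tr, sensor, i0:i1] += burst.astype(np.float32)

    epochs = EpochSet(data, config.fs_raw, labels, list(layout.channel_ids), t0)
    if config.artifact_rate > 0:
        epochs, art_truth = inject_artifacts(
            epochs, config.artifact_rate, seed=config.seed + 1, layout=layout
        )
        truth.artifact_trials = art_truth.artifact_trials
        truth.flat_channels = art_truth.flat_channels
    return epochs, truth


def inject_artifacts(
    epochs: EpochSet,
    rate: float,
    seed: int,
    layout: SensorLayout | None = None,
    n_frontal: int = 5,
    flat_channel: int | None = None,
) -> tuple[EpochSet, GroundTruth]:
    """Contaminate a fraction of trials with blink-like low-frequency transients.

    A ``rate`` fraction of trials (rounded) receives a < 4 Hz transient with
    peak amplitude 10x the median channel sd on the ``n_frontal`` frontal-most
    channels (largest y coordinate; the first channels when no layout is
    given). Optionally one channel is zeroed to emulate a dead sensor.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    truth = GroundTruth()
    out = epochs.copy()
    if flat_channel is not None:
        out.data[:, flat_channel, :] = 0.0
        truth.flat_channels = {int(flat_channel)}
    n_bad = int(round(rate * epochs.n_trials))
    if n_bad == 0:
        return out, truth
    rng = np.random.default_rng(seed)
    bad = rng.choice(epochs.n_trials, size=n_bad, replace=False)
    if layout is not None:
        frontal = np.argsort(layout.positions[:, 1])[::-1][:n_frontal]
    else:
        frontal = np.arange(min(n_frontal, epochs.n_channels))
    sd = float(np.median(out.data.astype(np.float64).std(axis=(0, 2))))
    # 0.5 s raised-cosine bump: spectral content well below 4 Hz
    width = int(round(0.5 * epochs.fs))
    bump = 10.0 * sd * np.hanning(width)
    for tr in bad:
        start = rng.integers(0, max(1, epochs.n_samples - width))
        for ch in frontal:
            out.data[tr, ch, start : start + width] += bump.astype(out.data.dtype)
    truth.artifact_trials = {int(i) for i in bad}
    return out, truth
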