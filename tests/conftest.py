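"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from megsense import (
    SimulationConfig,
    default_planted_map,
    extract_features,
    extract_window,
    make_layout,
    simulate_epochs,
)

#: Dyadic band edges (Hz) of the 7-level db4 decomposition at 1 kHz; these are
#: the operative cut-offs behind the nominal band names.
DYADIC_EDGES = {
    "high_gamma": (62.5, 125.0),
    "gamma": (31.25, 62.5),
    "beta": (15.625, 31.25),
    "alpha": (7.8125, 15.625),
    "theta": (3.90625, 7.8125),
    "delta": (0.0, 3.90625),
}


def fft_band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Independent band-power oracle: periodogram power summed over [lo, hi)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1 / fs)
    return float(spec[(f >= lo) & (f < hi)].sum())


def make_planted_dataset(
    n_sensors: int = 10,
    n_classes: int = 3,
    n_per_class: int = 9,
    n_informative: int = 4,
    amplitude: float = 3.0,
    seed: int = 0,
    stage: str = "production",
):
    """Small 1-kHz dataset (no raw-rate chain) plus features and ground truth."""
    layout = make_layout(n_sensors, seed=seed)
    config = SimulationConfig(
        n_sensors=n_sensors,
        n_classes=n_classes,
        n_trials_per_class=n_per_class,
        fs_raw=1000.0,
        planted_map=default_planted_map(n_classes, n_sensors, n_informative, amplitude),
        seed=seed,
    )
    epochs, truth = simulate_epochs(config, layout)
    window = extract_window(epochs, stage)
    features = extract_features(window)
    return layout, epochs, truth, features


@pytest.fixture(scope="session")
def planted():
    """10 sensors, 3 classes, 9 trials/class, 4 informative sensors."""
    layout, epochs, truth, features = make_planted_dataset(seed=7)
    return {"layout": layout, "epochs": epochs, "truth": truth, "features": features}


@pytest.fixture(scope="session")
def planted_features(planted):
    return planted["features"]
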