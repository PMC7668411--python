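"""HDF5/CSV/JSON persistence for epochs, layouts, features and results.

The epoch container is a single HDF5 file with datasets ``/data``,
``/labels``, ``/fs``, ``/time``, ``/channels``, ``/positions`` and the
planted ground truth under ``/truth/*``; sensor layouts round-trip through
CSV (channel_id, x, y, z, hemisphere). Epochs recorded with a Neuromag
system can optionally be imported from FIF files (gradiometers only) when
``mne`` is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from dataclasses import asdict

from .autoencoder import AEConfig, StackedAE
from .features import FeatureMatrix
from .preprocess import EpochSet
from .synth import GroundTruth, SensorLayout

__all__ = [
    "save_epochs",
    "load_epochs",
    "layout_to_csv",
    "layout_from_csv",
    "save_features",
    "load_features",
    "features_to_csv",
    "save_stack",
    "load_stack",
    "read_fif_epochs",
]


def save_epochs(
    path: str | Path,
    epochs: EpochSet,
    layout: SensorLayout | None = None,
    truth: GroundTruth | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("fs", data=float(epochs.fs))
        f.create_dataset("time", data=epochs.times)
        f.create_dataset("channels", data=np.array(epochs.channel_ids, dtype="S"))
        if layout is not None:
            f.create_dataset("positions", data=layout.positions)
            f.create_dataset(
                "hemispheres", data=np.array(layout.hemispheres, dtype="S")
            )
        if truth is not None:
            g = f.create_group("truth")
            g.attrs["informative_sensors"] = json.dumps(
                {str(k): sorted(v) for k, v in truth.informative_sensors.items()}
            )
            g.attrs["informative_bands"] = json.dumps(
                {str(k): sorted(v) for k, v in truth.informative_bands.items()}
            )
            g.create_dataset("artifact_trials", data=sorted(truth.artifact_trials))
            g.create_dataset("flat_channels", data=sorted(truth.flat_channels))


def load_epochs(path: str | Path) -> tuple[EpochSet, SensorLayout | None, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        t = f["time"][:]
        epochs = EpochSet(
            f["data"][:],
            float(f["fs"][()]),
            f["labels"][:],
            [c.decode() for c in f["channels"][:]],
            float(t[0]),
        )
        layout = None
        if "positions" in f:
            layout = SensorLayout(
                list(epochs.channel_ids),
                f["positions"][:],
                [h.decode() for h in f["hemispheres"][:]],
            )
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = GroundTruth(
                informative_sensors={
                    int(k): set(v)
                    for k, v in json.loads(g.attrs["informative_sensors"]).items()
                },
                informative_bands={
                    int(k): set(v)
                    for k, v in json.loads(g.attrs["informative_bands"]).items()
                },
                artifact_trials=set(int(i) for i in g["artifact_trials"][:]),
                flat_channels=set(int(i) for i in g["flat_channels"][:]),
            )
    return epochs, layout, truth


def layout_to_csv(path: str | Path, layout: SensorLayout) -> None:
    pd.DataFrame(
        {
            "channel_id": layout.channel_ids,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": layout.positions[:, 2],
            "hemisphere": layout.hemispheres,
        }
    ).to_csv(path, index=False)


def layout_from_csv(path: str | Path) -> SensorLayout:
    df = pd.read_csv(path)
    return SensorLayout(
        list(df["channel_id"]),
        df[["x", "y", "z"]].to_numpy(float),
        list(df["hemisphere"]),
    )


def save_features(path: str | Path, features: FeatureMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=features.values)
        f.create_dataset("labels", data=features.labels)
        f.create_dataset("sensors", data=np.array(features.sensor_ids, dtype="S"))
        f.attrs["bands"] = json.dumps(list(features.bands))


def load_features(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        return FeatureMatrix(
            f["values"][:],
            f["labels"][:],
            [s.decode() for s in f["sensors"][:]],
            tuple(json.loads(f.attrs["bands"])),
        )


def features_to_csv(path: str | Path, features: FeatureMatrix) -> None:
    """Write features as CSV with ``<sensorid>_<band>`` column headers."""
    df = pd.DataFrame(features.values, columns=features.column_names)
    df.insert(0, "label", features.labels)
    df.to_csv(path, index=False)


def save_stack(path: str | Path, stack: StackedAE) -> None:
    """Write a trained autoencoder stack to HDF5 with its config embedded."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(stack.config))
        f.create_dataset("classes", data=stack.classes)
        f.create_dataset("scaler/lo", data=stack.scaler[0])
        f.create_dataset("scaler/range", data=stack.scaler[1])
        for name, layers in (
            ("encoder", stack.encoder_weights),
            ("decoder", stack.decoder_weights),
        ):
            for i, (W, b) in enumerate(layers):
                f.create_dataset(f"{name}/{i}/W", data=W)
                f.create_dataset(f"{name}/{i}/b", data=b)
        f.create_dataset("softmax/W", data=stack.softmax_weights[0])
        f.create_dataset("softmax/b", data=stack.softmax_weights[1])


def load_stack(path: str | Path) -> StackedAE:
    with h5py.File(path, "r") as f:
        cfg = json.loads(f.attrs["config"])
        for key in ("layer_dims", "sparsity_proportion"):
            cfg[key] = tuple(cfg[key])
        if isinstance(cfg["l2_coeff"], list):
            cfg["l2_coeff"] = tuple(cfg["l2_coeff"])
        read = lambda g: [
            (f[f"{g}/{i}/W"][:], f[f"{g}/{i}/b"][:])
            for i in range(len(f[g]))
        ]
        return StackedAE(
            encoder_weights=read("encoder"),
            decoder_weights=read("decoder"),
            softmax_weights=(f["softmax/W"][:], f["softmax/b"][:]),
            scaler=(f["scaler/lo"][:], f["scaler/range"][:]),
            classes=f["classes"][:],
            config=AEConfig(**cfg),
        )


def read_fif_epochs(path: str | Path) -> EpochSet:
    """Import epochs from a Neuromag FIF file, gradiometer channels only.

    Requires the optional ``mne`` dependency.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading FIF files requires the 'mne' package") from exc
    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    ep = ep.pick("grad")
    events = ep.events[:, 2]
    return EpochSet(
        ep.get_data(copy=True),
        float(ep.info["sfreq"]),
        events,
        list(ep.ch_names),
        float(ep.tmin),
    )
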