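"""Comparison surfaces: selection curves, sensor maps and condition summaries.

"Subjects" in synthetic mode are independent generator seeds sharing the
planted structure, so across-subject means, standard errors and paired
tests can be computed against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decode import CVResult, TTestResult, paired_ttest
from .select import SelectionTrace
from .synth import SensorLayout

__all__ = ["ComparisonSummary", "selection_curve", "sensor_map", "summarize"]


@dataclass
class ComparisonSummary:
    """Across-subject mean, standard error and per-subject accuracies per condition."""

    conditions: dict[str, np.ndarray]  # name -> per-subject accuracies (%)
    ttests: dict[tuple[str, str], TTestResult]

    @property
    def means(self) -> dict[str, float]:
        return {k: float(np.mean(v)) for k, v in self.conditions.items()}

    @property
    def standard_errors(self) -> dict[str, float]:
        return {
            k: float(np.std(v, ddof=1) / np.sqrt(len(v)))
            for k, v in self.conditions.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": k,
                "mean": self.means[k],
                "se": self.standard_errors[k],
                "n_subjects": len(v),
            }
            for k, v in self.conditions.items()
        ]
        return pd.DataFrame(rows)


def selection_curve(
    traces: list[SelectionTrace],
) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject mean and sd of the per-step selection accuracy curves."""
    if not traces:
        raise ValueError("need at least one trace")
    lengths = {len(t.step_accuracy) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    curves = np.array([t.step_accuracy for t in traces], dtype=float)
    sd = curves.std(axis=0, ddof=1) if len(traces) > 1 else np.zeros(curves.shape[1])
    return curves.mean(axis=0), sd


def sensor_map(
    trace: SelectionTrace,
    layout: SensorLayout,
    top_k: int = 9,
    out_png: str | None = None,
) -> pd.DataFrame:
    """Axial-projection table (and optional plot) of the top-k ranked sensors.

    Returns a frame with (rank, sensor_id, hemisphere, x, y, z); if
    ``out_png`` is given, a 2-D x-y scatter with rank-coloured markers is
    written there.
    """
    if top_k > len(trace.ranked_sensors):
        raise ValueError("top_k exceeds trace length")
    pos = {c: (p, h) for c, p, h in zip(layout.channel_ids, layout.positions, layout.hemispheres)}
    rows = []
    for rank, sensor in enumerate(trace.ranked_sensors[:top_k], start=1):
        p, h = pos[sensor]
        rows.append(
            {"rank": rank, "sensor_id": sensor, "hemisphere": h,
             "x": p[0], "y": p[1], "z": p[2]}
        )
    frame = pd.DataFrame(rows)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(layout.positions[:, 0], layout.positions[:, 1], s=10, c="0.8")
        sc = ax.scatter(frame["x"], frame["y"], c=frame["rank"], cmap="jet", s=80)
        for _, r in frame.iterrows():
            ax.annotate(str(r["rank"]), (r["x"], r["y"]), fontsize=8)
        fig.colorbar(sc, ax=ax, label="rank")
        ax.set_xlabel("x (cm, left < 0)")
        ax.set_ylabel("y (cm, anterior)")
        ax.set_aspect("equal")
        fig.savefig(out_png, dpi=120)
        plt.close(fig)
    return frame


def summarize(
    conditions: dict[str, list[CVResult] | list[float]],
    pairs: list[tuple[str, str]] | None = None,
    tails: int = 2,
) -> ComparisonSummary:
    """Across-subject summary of named conditions with paired t-tests.

    Every condition must cover the same subjects (equal length, same order).
    """
    arrays: dict[str, np.ndarray] = {}
    for name, vals in conditions.items():
        accs = [v.mean_accuracy if isinstance(v, CVResult) else float(v) for v in vals]
        arrays[name] = np.asarray(accs, dtype=float)
    ns = {len(v) for v in arrays.values()}
    if len(ns) != 1:
        raise ValueError("conditions cover different numbers of subjects")
    ttests: dict[tuple[str, str], TTestResult] = {}
    for a, b in pairs or []:
        if a not in arrays or b not in arrays:
            raise ValueError(f"unknown condition in pair ({a}, {b})")
        ttests[(a, b)] = paired_ttest(arrays[a], arrays[b], tails=tails)
    return ComparisonSummary(arrays, ttests)
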