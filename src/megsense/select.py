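"""Step-wise greedy forward sensor selection with an SVM-CV objective.

Each sensor contributes a six-feature block (one RMS value per band).
Step 1 cross-validates every sensor alone and keeps the best; step t
appends each remaining sensor to the fixed optimal set O1..O(t-1),
re-evaluates, and keeps the sensor that maximises mean CV accuracy, up to
``K_max`` (default 50) sensors. Ties go to the lowest sensor index, and the
fold assignment is frozen across all steps so comparisons between candidate
sets are paired. Convergence ("plateau") is the first step after which the
accuracy curve strictly decreases — in the emulated study that happened
when the optimal set grew from 9 to 10 sensors.

Mode (consensus) analysis counts, for each sensor, how many subjects
include it in their top-k ranking — the spatially consistent sensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decode import CVResult, DecoderConfig, crossval_svm, make_folds
from .features import FeatureMatrix, subset_features

__all__ = [
    "SelectionTrace",
    "forward_select",
    "find_plateau",
    "consensus",
]


@dataclass
class SelectionTrace:
    """Ordered selected sensors O1..OK with the per-step mean CV accuracy (%)."""

    ranked_sensors: list[str]
    step_accuracy: list[float]
    K_max: int
    sensor_universe: list[str] = field(default_factory=list)
    evaluations_per_step: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ranked_sensors)) != len(self.ranked_sensors):
            raise ValueError("ranked sensors must be distinct")
        if len(self.step_accuracy) != len(self.ranked_sensors):
            raise ValueError("one accuracy per selection step required")

    @property
    def plateau_step(self) -> int | None:
        return find_plateau(self)

    def to_dict(self) -> dict:
        return {
            "ranked_sensors": list(self.ranked_sensors),
            "step_accuracy": [float(a) for a in self.step_accuracy],
            "K_max": self.K_max,
            "sensor_universe": list(self.sensor_universe),
            "plateau_step": self.plateau_step,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_sensors) + 1),
                "sensor_id": self.ranked_sensors,
                "accuracy": self.step_accuracy,
            }
        )


def forward_select(
    features: FeatureMatrix,
    config: DecoderConfig | None = None,
    K_max: int = 50,
    fold_assignment: np.ndarray | None = None,
) -> SelectionTrace:
    """Greedy forward selection of sensor blocks maximising mean CV accuracy.

    Step t evaluates exactly ``n_sensors - t + 1`` candidate sets; candidate
    evaluations within a step are independent of each other, and the argmax
    is taken in sensor order so ties resolve to the lowest index.
    """
    if config is None:
        config = DecoderConfig()
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if K_max > len(features.sensor_ids):
        raise ValueError("K_max exceeds the number of sensors")
    if fold_assignment is None:
        fold_assignment = make_folds(features.labels, config.folds, config.seed)

    selected: list[str] = []
    remaining = list(features.sensor_ids)
    accuracies: list[float] = []
    evals: list[int] = []
    for _step in range(K_max):
        best_acc = -np.inf
        best_sensor = None
        for cand in remaining:
            sub = subset_features(features, selected + [cand])
            acc = crossval_svm(sub, config, fold_assignment).mean_accuracy
            if acc > best_acc:  # strict: first (lowest-index) max wins ties
                best_acc = acc
                best_sensor = cand
        selected.append(best_sensor)
        remaining.remove(best_sensor)
        accuracies.append(best_acc)
        evals.append(len(remaining) + 1)
    return SelectionTrace(
        ranked_sensors=selected,
        step_accuracy=accuracies,
        K_max=K_max,
        sensor_universe=list(features.sensor_ids),
        evaluations_per_step=evals,
    )


def find_plateau(trace: SelectionTrace | list[float]) -> int | None:
    """First step t (1-based) whose successor's accuracy strictly decreases.

    Returns None for a monotone non-decreasing (or constant) curve.
    """
    acc = trace.step_accuracy if isinstance(trace, SelectionTrace) else list(trace)
    if len(acc) == 0:
        raise ValueError("trace must be non-empty")
    for t in range(len(acc) - 1):
        if acc[t + 1] < acc[t]:
            return t + 1
    return None


def consensus(traces: list[SelectionTrace], k: int = 50) -> pd.Series:
    """Per-sensor count of subjects including it in their top-k ranking.

    All traces must share a sensor universe and reach at least ``k`` ranks.
    Returned sorted by descending count (ties by sensor id).
    """
    if not traces:
        raise ValueError("need at least one trace")
    universe = set(traces[0].sensor_universe)
    for tr in traces[1:]:
        if set(tr.sensor_universe) != universe:
            raise ValueError("traces have inconsistent sensor universes")
    counts: dict[str, int] = {}
    for tr in traces:
        if len(tr.ranked_sensors) < k:
            raise ValueError(f"trace has fewer than k={k} ranks")
        for s in tr.ranked_sensors[:k]:
            counts[s] = counts.get(s, 0) + 1
    series = pd.Series(counts, name="mode")
    return series.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
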