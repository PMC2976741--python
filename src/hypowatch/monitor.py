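"""Minute-by-minute continuous prediction over a whole record.

At each minute ``t`` the observation window ``[t - obs, t)`` is checked for
validity, featurized, reduced, and fed to a trained classifier/regressor
pair. The emitted probability of hypotension and predicted median MAP refer
to the 30-minute target window starting at ``t + gap`` — i.e. predictions
are made ``gap`` minutes ahead. Minutes whose observation window is
incomplete (record start) or fails the in-bound validity rule carry a
no-prediction flag instead, mirroring the gaps a bedside implementation
would show on missing or artifact-laden input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import features_from_slices
from .models import ClassifierModel, RegressorModel, predict_map, predict_probability
from .records import HemodynamicRecord
from .reduce import FittedReducer, apply_reducer
from .windows import SERIES_NAMES, WindowSpec, check_observation_validity

__all__ = ["MonitorTrace", "continuous_predict", "align_trace_for_plotting"]

REASON_WARMUP = "incomplete-observation-window"
REASON_INVALID = "invalid-observation-data"


@dataclass
class MonitorTrace:
    """Per-minute predictions for one record.

    ``probability[t]`` / ``predicted_map[t]`` apply to the target window
    starting at ``t + gap``; ``no_prediction_reason[t]`` is None where a
    prediction exists.
    """

    record_id: str
    spec: WindowSpec
    probability: np.ndarray  # NaN where no prediction
    predicted_map: np.ndarray
    no_prediction_reason: list[str | None]

    def __len__(self) -> int:
        return len(self.probability)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "minute": np.arange(len(self)),
                "probability": self.probability,
                "predicted_map": self.predicted_map,
                "no_prediction_reason": self.no_prediction_reason,
            }
        )


def continuous_predict(
    record: HemodynamicRecord,
    classifier: ClassifierModel,
    regressor: RegressorModel,
    reducer: FittedReducer,
    spec: WindowSpec,
) -> MonitorTrace:
    """Run the full pipeline at every minute of the record.

    Equivalent, minute for minute, to compiling a one-off example with
    ``target_start = t + gap`` and scoring it — the models and reducer must
    have been trained under the same window spec.
    """
    if classifier.n_inputs != reducer.k or regressor.n_inputs != reducer.k:
        raise ValueError(
            "model input sizes do not match the reducer's retained components"
        )
    n = record.n_minutes
    obs = spec.obs_minutes
    probability = np.full(n, np.nan)
    predicted = np.full(n, np.nan)
    reasons: list[str | None] = [None] * n

    feature_rows = []
    minutes = []
    for t in range(n):
        if t < obs:
            reasons[t] = REASON_WARMUP
            continue
        slices = {name: record.series(name)[t - obs : t] for name in SERIES_NAMES}
        if not check_observation_validity(slices):
            reasons[t] = REASON_INVALID
            continue
        feature_rows.append(
            features_from_slices(slices, record.age, record.medications, t - obs, t)
        )
        minutes.append(t)

    if minutes:
        reduced = apply_reducer(reducer, np.array(feature_rows))
        probability[minutes] = predict_probability(classifier, reduced)
        predicted[minutes] = predict_map(regressor, reduced)

    return MonitorTrace(
        record_id=record.record_id,
        spec=spec,
        probability=probability,
        predicted_map=predicted,
        no_prediction_reason=reasons,
    )


def shift_series(values: np.ndarray, shift: int) -> np.ndarray:
    """Shift a series forward by ``shift`` minutes (NaN-padded, same length)."""
    out = np.full_like(np.asarray(values, dtype=float), np.nan)
    if shift >= 0:
        if shift < len(out):
            out[shift:] = values[: len(out) - shift]
    else:
        out[:shift] = values[-shift:]
    return out


def align_trace_for_plotting(trace: MonitorTrace, spec: WindowSpec) -> np.ndarray:
    """MAP predictions shifted forward by the gap, for overlay on the true MAP.

    A prediction emitted at minute ``t`` describes the window starting at
    ``t + gap``; shifting removes that offset so predicted and true MAP can
    be compared on one axis. Probabilities are deliberately left unshifted
    (their lead time is the point), so only the MAP series is returned.
    """
    return shift_series(trace.predicted_map, spec.gap_minutes)


def plot_trace(
    record: HemodynamicRecord,
    trace: MonitorTrace,
    spec: WindowSpec,
    path: str | None = None,
):
    """Two-panel convenience plot: true + gap-shifted predicted MAP, then
    the probability of impending hypotension with the 60 mmHg line marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    minutes = np.arange(record.n_minutes) / 60.0
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(10, 6))
    ax1.plot(minutes, record.map, lw=0.6, label="true MAP")
    ax1.plot(minutes, align_trace_for_plotting(trace, spec), lw=0.8, label="predicted MAP (shifted)")
    ax1.axhline(60.0, ls="--", c="k", lw=0.8)
    ax1.set_ylabel("MAP (mmHg)")
    ax1.legend(loc="upper right", fontsize=8)
    ax2.plot(minutes, trace.probability, lw=0.8, c="tab:red")
    ax2.set_ylabel("P(hypotension)")
    ax2.set_xlabel("time (h)")
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
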