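"""Closed-loop simulation of cardiac-gated stimulus scheduling.

Each trial waits for a fixed number of fresh heartbeats (the variable
inter-trial interval), predicts the next R-wave from the last three
detected beats, and presents the stimulus at a fixed offset after the
*predicted* R-wave: ~300 ms to land at the end of systole, ~500 ms to
land in diastole.  Because the prediction can err, the trial's true
cardiac phase is determined afterwards from the distance between the
actual onset and the nearest *actual* preceding R-wave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ecg_events import RWaveSeries, predict_next_r

__all__ = ["GatingParams", "schedule_onset", "run_closed_loop"]

PHASES = ("systole", "diastole")


@dataclass(frozen=True)
class GatingParams:
    """Stimulus scheduling settings.

    Offsets are milliseconds after the predicted R-wave: 300 ms targets
    the end of the systolic pressure wave (maximal baroreceptor firing),
    500 ms the diastolic quiescence.
    """

    systole_offset_ms: float = 300.0
    diastole_offset_ms: float = 500.0
    min_beats_between_trials: int = 4
    detection_latency_ms: float = 1.0
    predictor: str = "mean"

    def __post_init__(self) -> None:
        if self.systole_offset_ms <= 0 or self.diastole_offset_ms <= 0:
            raise ValueError("phase offsets must be positive")
        if self.systole_offset_ms >= self.diastole_offset_ms:
            raise ValueError("systole offset must precede diastole offset")
        if self.min_beats_between_trials < 1:
            raise ValueError("min_beats_between_trials must be >= 1")
        if self.detection_latency_ms < 0:
            raise ValueError("detection_latency_ms must be non-negative")

    def offset(self, phase: str) -> float:
        if phase == "systole":
            return self.systole_offset_ms
        if phase == "diastole":
            return self.diastole_offset_ms
        raise ValueError(f"unknown cardiac phase: {phase!r}")


def schedule_onset(
    predicted_r: float, intended_phase: str, params: GatingParams | None = None
) -> float:
    """Intended stimulus onset: predicted R-wave time plus the phase offset."""
    params = params or GatingParams()
    return float(predicted_r) + params.offset(intended_phase)


def run_closed_loop(
    series: RWaveSeries,
    trials: pd.DataFrame,
    params: GatingParams | None = None,
) -> pd.DataFrame:
    """Schedule every trial of ``trials`` against the heartbeat stream.

    ``trials`` must carry an ``intended_phase`` column; rows are consumed
    in order.  For each trial the loop counts ``min_beats_between_trials``
    beats occurring after the previous trial's onset, predicts the next
    R-wave from the last three of them, and schedules the onset at the
    phase offset.  The returned copy gains columns:

    - ``predicted_r_ms`` — extrapolated next R-wave time
    - ``onset_ms`` — actual stimulus onset
    - ``prev_r_ms`` — nearest actual R-wave at or before onset
    - ``latency_ms`` — onset minus ``prev_r_ms`` (the recoding input)
    - ``beats_consumed`` — beats used up by the trial's inter-trial wait

    If the heartbeat stream runs out, the result is truncated to the
    trials that could be scheduled and ``attrs["truncated"]`` is True.
    """
    params = params or GatingParams()
    times = series.times
    k = params.min_beats_between_trials
    if times.size < k + 1:
        raise ValueError("heartbeat series too short for a single trial")

    out_rows = []
    cursor = 0  # index of next not-yet-counted beat
    marker = -np.inf  # beats are counted strictly after this moment
    truncated = False
    for row in trials.itertuples(index=False):
        phase = row.intended_phase
        start = cursor
        while cursor < times.size and times[cursor] <= marker:
            cursor += 1
        if cursor + k > times.size:
            truncated = True
            break
        counted = times[cursor : cursor + k]
        cursor += k
        beats_consumed = cursor - start
        # scheduling decision happens once the k-th beat is registered
        decision_time = counted[-1] + params.detection_latency_ms
        n_pred = 4 if params.predictor == "mean3" else 3
        pred = predict_next_r(times[cursor - n_pred : cursor], params.predictor)
        onset = schedule_onset(pred, phase, params)
        if onset < decision_time:  # cannot present in the past
            onset = decision_time
        prev_idx = np.searchsorted(times, onset, side="right") - 1
        if prev_idx + 1 >= times.size:
            # onset beyond the last recorded beat: latency unverifiable
            truncated = True
            break
        prev_r = times[prev_idx]
        out_rows.append(
            {
                **row._asdict(),
                "predicted_r_ms": pred,
                "onset_ms": onset,
                "prev_r_ms": prev_r,
                "latency_ms": onset - prev_r,
                "beats_consumed": beats_consumed,
            }
        )
        marker = onset
    if truncated:
        warnings.warn(
            f"heartbeat stream exhausted after {len(out_rows)} of "
            f"{len(trials)} trials",
            stacklevel=2,
        )
    out = pd.DataFrame(out_rows)
    out.attrs["truncated"] = truncated
    out.attrs["beats_consumed"] = int(cursor)
    return out
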