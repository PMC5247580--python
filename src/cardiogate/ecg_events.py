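"""R-wave event series, threshold-based detection and next-beat prediction.

The gating hardware this module emulates marks a heartbeat when the ECG
amplitude crosses an individually set threshold, and — because the stimulus
stream must be scheduled *before* the reference beat occurs — extrapolates
the time of the next R-wave from the three R-waves just observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RWaveSeries",
    "DetectorParams",
    "detect_r_waves",
    "predict_next_r",
    "prediction_error_profile",
    "PredictionErrorProfile",
]


@dataclass(frozen=True)
class RWaveSeries:
    """Strictly increasing R-peak event times (ms) for one recording.

    Parameters
    ----------
    times : array-like of float
        Event times in milliseconds since recording start.
    sampling_note : str
        Nominal time resolution of the source recording.
    meta : dict
        Free-form provenance (realized IBI statistics, clamp rate, ...).
    """

    times: np.ndarray
    sampling_note: str = "1 ms (1000 Hz recording)"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("R-wave times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.times.size)

    @property
    def ibis(self) -> np.ndarray:
        """Inter-beat intervals (ms)."""
        return np.diff(self.times)


@dataclass(frozen=True)
class DetectorParams:
    """Threshold-comparator R-wave detector settings.

    ``detection_latency_ms`` emulates the online processing delay between
    the physical R-peak and the logic pulse reaching the scheduler; the
    hardware bound is under 2 ms.
    """

    amplitude_threshold: float = 0.5
    refractory_ms: float = 250.0
    detection_latency_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.detection_latency_ms < 0:
            raise ValueError("detection_latency_ms must be non-negative")


def detect_r_waves(
    trace: np.ndarray,
    sample_period_ms: float,
    params: DetectorParams | None = None,
) -> RWaveSeries:
    """Detect R-waves as upward threshold crossings of a sampled trace.

    The event time is the time of the first sample at or above threshold
    (a comparator, not an interpolated peak).  Crossings inside the
    refractory period of the previous event are ignored.

    Returns an empty series (with a warning) when no beat is found.
    """
    params = params or DetectorParams()
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("trace is empty")
    if sample_period_ms <= 0:
        raise ValueError("sample_period_ms must be positive")
    if not (x.min() < params.amplitude_threshold <= x.max()):
        warnings.warn(
            "amplitude threshold outside signal range: no beats detected",
            stacklevel=2,
        )
        return RWaveSeries(times=np.empty(0), meta={"n_detected": 0})

    above = x >= params.amplitude_threshold
    # upward crossings: first sample of each supra-threshold run
    crossing = above & ~np.concatenate(([False], above[:-1]))
    cand = np.flatnonzero(crossing) * sample_period_ms
    events: list[float] = []
    for t in cand:
        if not events or t - events[-1] > params.refractory_ms:
            events.append(float(t))
    if not events:
        warnings.warn("no beats detected", stacklevel=2)
    return RWaveSeries(times=np.asarray(events), meta={"n_detected": len(events)})


def predict_next_r(recent, strategy: str = "mean") -> float:
    """Predict the next R-wave time from the preceding R-wave times.

    Strategies (``recent`` holds 3 event times except where noted):

    - ``"mean"`` (default): t3 + mean of the two observed IBIs.
    - ``"last"``: t3 + most recent IBI.
    - ``"linear"``: linear extrapolation of the IBI trend,
      t3 + 2*(t3-t2) - (t2-t1).
    - ``"mean3"``: four event times, t4 + mean of the three IBIs.
    """
    t = np.asarray(recent, dtype=float)
    expected = 4 if strategy == "mean3" else 3
    if t.shape != (expected,):
        raise ValueError(
            f"strategy {strategy!r} requires exactly {expected} event times"
        )
    if not np.all(np.diff(t) > 0):
        raise ValueError("R-wave times must be strictly increasing")
    if strategy == "mean":
        return float(t[2] + (t[2] - t[0]) / 2.0)
    if strategy == "last":
        return float(2 * t[2] - t[1])
    if strategy == "linear":
        return float(t[2] + 2 * (t[2] - t[1]) - (t[1] - t[0]))
    if strategy == "mean3":
        return float(t[3] + (t[3] - t[0]) / 3.0)
    raise ValueError(f"unknown prediction strategy: {strategy!r}")


@dataclass(frozen=True)
class PredictionErrorProfile:
    """Signed per-beat prediction errors (actual - predicted), ms."""

    errors: pd.DataFrame  # columns: beat_index, predicted_ms, actual_ms, error_ms
    mean: float
    sd: float


def prediction_error_profile(
    series: RWaveSeries, strategy: str = "mean"
) -> PredictionErrorProfile:
    """Offline reliability check of the next-beat predictor.

    For every beat k >= 4 (1-based) the predictor is run on the three
    preceding beats and compared against the beat that actually occurred.
    """
    t = series.times
    w = 4 if strategy == "mean3" else 3
    if t.size < w + 1:
        raise ValueError(f"need at least {w + 1} beats")
    rows = []
    for k in range(w, t.size):
        pred = predict_next_r(t[k - w : k], strategy=strategy)
        rows.append((k, pred, t[k], t[k] - pred))
    df = pd.DataFrame(
        rows, columns=["beat_index", "predicted_ms", "actual_ms", "error_ms"]
    )
    err = df["error_ms"].to_numpy()
    sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
    return PredictionErrorProfile(errors=df, mean=float(np.mean(err)), sd=sd)
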