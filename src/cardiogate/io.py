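"""Plain-text I/O: R-peak tables, annotation exports, trial logs, config.

All event times are integer-rounded milliseconds at the file boundary;
internal computation keeps full precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg_events import RWaveSeries

__all__ = [
    "write_rwave_table",
    "read_rwave_table",
    "write_annotations",
    "read_annotations",
    "write_trials",
    "read_trials",
    "load_config",
]


def write_rwave_table(series_by_subject: dict[str, RWaveSeries], path) -> None:
    """Two-column (subject_id, r_time_ms) CSV covering all subjects."""
    frames = [
        pd.DataFrame(
            {"subject_id": sid, "r_time_ms": np.rint(s.times).astype(int)}
        )
        for sid, s in series_by_subject.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_rwave_table(path) -> dict[str, RWaveSeries]:
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        out[str(sid)] = RWaveSeries(times=grp["r_time_ms"].to_numpy(dtype=float))
    return out


def write_annotations(
    series: RWaveSeries, path, sample_period_ms: float = 1.0, symbol: str = "N"
) -> None:
    """Annotation-style text export: one beat per line.

    Columns (whitespace separated): time in ms, sample index at the
    recording's nominal resolution, beat symbol — the layout of a text
    dump of a beat annotation file.
    """
    with open(path, "w") as fh:
        fh.write("# time_ms sample symbol\n")
        for t in series.times:
            fh.write(f"{int(round(t))} {int(round(t / sample_period_ms))} {symbol}\n")


def read_annotations(path, sample_period_ms: float = 1.0) -> RWaveSeries:
    times = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        times.append(float(line.split()[0]))
    return RWaveSeries(times=np.asarray(times, dtype=float))


_TIME_COLS = ("onset_ms", "prev_r_ms", "latency_ms", "predicted_r_ms", "rt_ms")


def write_trials(trials: pd.DataFrame, path) -> None:
    """Delimited trial log with integer-ms times."""
    out = trials.copy()
    for c in _TIME_COLS:
        if c in out.columns:
            out[c] = out[c].round(0).astype("Int64")
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load the declarative YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a key-value mapping")
    return cfg
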