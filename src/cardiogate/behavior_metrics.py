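"""Per-subject behavioral indices: accuracy, signal detection, process
dissociation, and shooter-task point payoffs.

Conventions
-----------
Accuracy is on-time correct responses over valid (non-excluded) trials;
late and missing responses count against it.  Signal-detection hit and
false-alarm rates are derived from the same accuracies: the hit rate is
the accuracy on signal-object trials (weapons / armed / sport objects)
and the false-alarm rate is one minus the accuracy on noise-object
trials.  Process-dissociation control is congruent-trial accuracy minus
incongruent-trial error; the automatic estimate is the incongruent
error rate divided by (1 - control).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic_data import DesignSpec

__all__ = [
    "accuracy_table",
    "sdt_indices",
    "sdt_table",
    "pdp_indices",
    "pdp_table",
    "fpst_points",
]


def accuracy_table(trials: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Per-subject, per-cell accuracy over valid (non-excluded) trials.

    Cells are (prime, object, recoded phase).  A cell with no valid
    trials yields NaN accuracy (flagged missing, never 0).  Columns:
    subject_id, prime, object, phase, n_trials, n_on_time_correct,
    accuracy.
    """
    req = {"recoded_phase", "on_time", "correct"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns: {sorted(missing)}")
    valid = trials[trials["recoded_phase"].isin(design.phases)].copy()
    valid["otc"] = valid["on_time"] & valid["correct"]
    grp = (
        valid.groupby(["subject_id", "prime", "object", "recoded_phase"])["otc"]
        .agg(n_trials="size", n_on_time_correct="sum")
        .reset_index()
        .rename(columns={"recoded_phase": "phase"})
    )
    grid = pd.MultiIndex.from_product(
        [sorted(trials["subject_id"].unique()), design.primes, design.objects,
         design.phases],
        names=["subject_id", "prime", "object", "phase"],
    )
    grp = (
        grp.set_index(["subject_id", "prime", "object", "phase"])
        .reindex(grid)
        .reset_index()
    )
    grp["accuracy"] = grp["n_on_time_correct"] / grp["n_trials"]
    return grp


def _correct_rate(rate: float, n: int, correction: str) -> float:
    if correction == "1/2N":
        lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
        return min(max(rate, lo), hi)
    if correction == "loglinear":
        return (rate * n + 0.5) / (n + 1.0)
    if correction == "none":
        return rate
    raise ValueError(f"unknown extreme-rate correction: {correction!r}")


def sdt_indices(
    hit_rate: float,
    fa_rate: float,
    n_signal: int,
    n_noise: int,
    correction: str = "1/2N",
) -> tuple[float, float]:
    """Sensitivity d' and criterion C from hit and false-alarm rates.

    d' = z(H) - z(F); C = -(z(H) + z(F)) / 2, z the standard normal
    quantile.  Rates of exactly 0 or 1 are corrected before the
    transform: the default 1/(2N) rule replaces 1 by 1 - 1/(2N) and 0 by
    1/(2N); the log-linear rule ((count + 0.5)/(N + 1), applied to every
    rate) is available as ``correction="loglinear"``.
    """
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if n_signal <= 0 or n_noise <= 0:
        raise ValueError("n_signal and n_noise must be positive")
    h = _correct_rate(float(hit_rate), n_signal, correction)
    f = _correct_rate(float(fa_rate), n_noise, correction)
    zh, zf = norm.ppf(h), norm.ppf(f)
    return float(zh - zf), float(-(zh + zf) / 2.0)


def sdt_table(
    acc: pd.DataFrame, design: DesignSpec, correction: str = "1/2N"
) -> pd.DataFrame:
    """Per-subject d' and C as a function of prime and cardiac phase.

    The object factor collapses into signal/noise roles: hits come from
    the design's signal object, false alarms from errors on the other
    object.
    """
    signal = design.signal_object
    noise = next(o for o in design.objects if o != signal)
    wide = acc.pivot_table(
        index=["subject_id", "prime", "phase"],
        columns="object",
        values=["accuracy", "n_trials"],
        aggfunc="first",
    )
    rows = []
    for (sid, prime, phase), r in wide.iterrows():
        h = r[("accuracy", signal)]
        f = 1.0 - r[("accuracy", noise)]
        ns, nn = r[("n_trials", signal)], r[("n_trials", noise)]
        if np.isnan(h) or np.isnan(f):
            d = c = np.nan
        else:
            d, c = sdt_indices(h, f, int(ns), int(nn), correction)
        rows.append(
            {
                "subject_id": sid,
                "prime": prime,
                "phase": phase,
                "hit_rate": h,
                "fa_rate": f,
                "d_prime": d,
                "criterion_c": c,
            }
        )
    return pd.DataFrame(rows)


def pdp_indices(acc_congruent: float, err_incongruent: float) -> tuple[float, float]:
    """Process-dissociation control and automatic estimates.

    control = congruent accuracy - incongruent error rate;
    automatic = incongruent error rate / (1 - control).  When control
    equals 1 the automatic estimate is undefined and returned as NaN.
    """
    if not (0 <= acc_congruent <= 1 and 0 <= err_incongruent <= 1):
        raise ValueError("inputs must lie in [0, 1]")
    control = acc_congruent - err_incongruent
    if control >= 1.0:
        return float(control), float("nan")
    automatic = err_incongruent / (1.0 - control)
    return float(control), float(automatic)


def pdp_table(acc: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Per-subject PDP estimates, separately per prime and cardiac phase.

    For each prime the congruent cell is its stereotype-consistent
    object (e.g. black-weapon, white-tool in the WIT) and the
    incongruent error rate comes from the other object's cell.
    """
    wide = acc.pivot_table(
        index=["subject_id", "prime", "phase"],
        columns="object",
        values="accuracy",
        aggfunc="first",
    )
    rows = []
    for (sid, prime, phase), r in wide.iterrows():
        cong = design.congruent[prime]
        incong = next(o for o in design.objects if o != cong)
        a, e = r[cong], 1.0 - r[incong]
        if np.isnan(a) or np.isnan(e):
            control = automatic = np.nan
        else:
            control, automatic = pdp_indices(a, e)
        rows.append(
            {
                "subject_id": sid,
                "prime": prime,
                "phase": phase,
                "control": control,
                "automatic": automatic,
            }
        )
    return pd.DataFrame(rows)


def fpst_points(
    trials: pd.DataFrame, design: DesignSpec | None = None
) -> pd.DataFrame:
    """Per-subject point totals for the first-person shooter task.

    Payoffs: +10 shooting armed, +5 sparing unarmed, -20 shooting
    unarmed, -40 sparing armed, -10 for failing to answer within the
    650 ms deadline (responses arriving between the deadline and the end
    of the collection window score as timeouts — the points feedback
    used the deadline).  The shoot/don't-shoot response is reconstructed
    from the object and correctness columns.
    """
    design = design or DesignSpec.fpst()
    if design.payoff is None:
        raise ValueError("design has no payoff matrix (not an FPST design)")
    unknown = set(trials["object"].unique()) - set(design.objects)
    if unknown:
        raise ValueError(f"unknown outcome objects: {sorted(unknown)}")
    armed = trials["object"] == design.signal_object
    timeout = ~(trials["on_time"].astype(bool))
    shoot = np.where(armed, trials["correct"], ~trials["correct"].astype(bool))
    outcome = np.select(
        [timeout, armed & shoot, armed & ~shoot, ~armed & shoot],
        ["timeout", "armed_shoot", "armed_noshoot", "unarmed_shoot"],
        default="unarmed_noshoot",
    )
    pts = pd.Series(outcome).map(design.payoff).to_numpy()
    out = (
        trials.assign(points=pts)
        .groupby("subject_id")["points"]
        .agg(n_trials="size", points="sum")
        .reset_index()
    )
    return out
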