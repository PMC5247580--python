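"""Synthetic cohorts for cardiac-gated priming tasks.

The original participant data are not public, so this module generates
everything downstream stages need: inter-beat-interval series with
realistic variability (Gaussian AR(1) around a mean IBI, optional
respiratory sinusoid), the trial economies of the three task designs,
and per-condition Bernoulli response accuracy with a configurable
prime x object x cardiac-phase interaction plus a lognormal
response-latency / miss model.

Factor levels
-------------
prime/race: ``black`` / ``white``; cardiac phase: ``systole`` /
``diastole``; objects are task specific — ``tool``/``weapon`` (weapons
identification task, WIT), ``unarmed``/``armed`` (first-person shooter
task, FPST), ``fruit``/``sport`` (sport-fruits identification task,
SFIT).  A cell is the tuple ``(prime, object, phase)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ecg_events import RWaveSeries
from .gating import GatingParams, run_closed_loop
from .phase_recode import PhaseWindows, recode_trials

__all__ = [
    "IBI_FLOOR_MS",
    "HeartModelParams",
    "DesignSpec",
    "BehaviorModelParams",
    "generate_rwave_series",
    "generate_trial_sequence",
    "simulate_responses",
    "generate_cohort",
    "simulate_cell_accuracies",
    "synthesize_ecg_trace",
    "Cohort",
    "SubjectData",
    "default_p_correct",
]

#: physiological lower bound on a credible inter-beat interval
IBI_FLOOR_MS = 300.0

PRIMES = ("black", "white")
PHASES = ("systole", "diastole")


@dataclass(frozen=True)
class HeartModelParams:
    """Gaussian AR(1) inter-beat-interval model.

    ``mean_ibi`` (ms) sets heart rate (850 ms ~ 71 bpm), ``sdnn`` the
    stationary IBI standard deviation, ``ar1`` the lag-1 autocorrelation.
    ``rsa_amp``/``rsa_freq`` add an optional sinusoidal respiratory
    modulation (amplitude in ms, frequency in Hz).  IBIs below the
    physiological floor are clamped and the clamping rate is reported in
    the series metadata.
    """

    mean_ibi: float = 850.0
    sdnn: float = 30.0
    ar1: float = 0.0
    rsa_amp: float = 0.0
    rsa_freq: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_ibi <= IBI_FLOOR_MS:
            raise ValueError(
                f"mean_ibi must exceed the physiological floor ({IBI_FLOOR_MS} ms)"
            )
        if self.sdnn < 0:
            raise ValueError("sdnn must be non-negative")
        if not -1 < self.ar1 < 1:
            raise ValueError("ar1 must lie in (-1, 1)")
        if self.rsa_amp < 0 or self.rsa_freq <= 0:
            raise ValueError("rsa_amp must be >= 0 and rsa_freq > 0")


@dataclass(frozen=True)
class DesignSpec:
    """One task's factorial structure, timings and trial economy.

    ``gated_stimulus`` names which display element is locked to the
    cardiac phase (the prime for WIT/SFIT, the target for FPST);
    ``signal_object`` is the object treated as "signal" in the
    signal-detection analysis; ``congruent`` maps each prime to its
    stereotype-congruent object.
    """

    task_id: str
    objects: tuple[str, str]
    trials_per_cell: int
    pre_stimulus_mask_ms: float
    stimulus_ms: float
    post_mask_ms: float
    response_deadline_ms: float
    collection_window_ms: float
    gated_stimulus: str
    signal_object: str
    congruent: Mapping[str, str]
    payoff: Mapping[str, float] | None = None
    min_beats_between_trials: int = 4
    primes: tuple[str, str] = PRIMES
    phases: tuple[str, str] = PHASES

    def __post_init__(self) -> None:
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if self.signal_object not in self.objects:
            raise ValueError("signal_object must be one of the task's objects")
        for d in (
            self.stimulus_ms,
            self.response_deadline_ms,
            self.collection_window_ms,
        ):
            if d <= 0:
                raise ValueError("durations must be positive")

    @property
    def cells(self) -> list[tuple[str, str, str]]:
        return [
            (p, o, ph)
            for p in self.primes
            for o in self.objects
            for ph in self.phases
        ]

    @property
    def n_trials(self) -> int:
        return self.trials_per_cell * len(self.cells)

    def replace(self, **kw) -> "DesignSpec":
        return replace(self, **kw)

    @classmethod
    def wit(cls, **kw) -> "DesignSpec":
        """Weapons identification task: 264 trials, 33 per cell.

        200 ms prime (cardiac-gated), 150 ms target, 500 ms response
        deadline, responses collected up to 650 ms.
        """
        spec = cls(
            task_id="WIT",
            objects=("tool", "weapon"),
            trials_per_cell=33,
            pre_stimulus_mask_ms=600.0,
            stimulus_ms=200.0,
            post_mask_ms=300.0,
            response_deadline_ms=500.0,
            collection_window_ms=650.0,
            gated_stimulus="prime",
            signal_object="weapon",
            congruent={"black": "weapon", "white": "tool"},
        )
        return spec.replace(**kw) if kw else spec

    @classmethod
    def fpst(cls, **kw) -> "DesignSpec":
        """First-person shooter task: 23 trials per cell (184 total).

        200 ms target (cardiac-gated) over a 400-500 ms background,
        650 ms deadline, responses collected up to 1000 ms, point payoffs
        rewarding shooting armed and sparing unarmed targets.
        """
        spec = cls(
            task_id="FPST",
            objects=("unarmed", "armed"),
            trials_per_cell=23,
            pre_stimulus_mask_ms=450.0,
            stimulus_ms=200.0,
            post_mask_ms=0.0,
            response_deadline_ms=650.0,
            collection_window_ms=1000.0,
            gated_stimulus="target",
            signal_object="armed",
            congruent={"black": "armed", "white": "unarmed"},
            payoff={
                "armed_shoot": 10.0,
                "unarmed_noshoot": 5.0,
                "unarmed_shoot": -20.0,
                "armed_noshoot": -40.0,
                "timeout": -10.0,
            },
        )
        return spec.replace(**kw) if kw else spec

    @classmethod
    def sfit(cls, **kw) -> "DesignSpec":
        """Sport-fruits identification task: WIT timings, positive stereotype."""
        spec = cls.wit().replace(
            task_id="SFIT",
            objects=("fruit", "sport"),
            signal_object="sport",
            congruent={"black": "sport", "white": "fruit"},
        )
        return spec.replace(**kw) if kw else spec

    @classmethod
    def from_task_id(cls, task_id: str, **kw) -> "DesignSpec":
        factories = {"wit": cls.wit, "fpst": cls.fpst, "sfit": cls.sfit}
        try:
            return factories[task_id.lower()](**kw)
        except KeyError:
            raise ValueError(f"unknown task_id: {task_id!r}") from None


def default_p_correct(
    task_id: str, phase_effect: bool | None = None
) -> dict[tuple[str, str, str], float]:
    """Default per-cell accuracy maps encoding each task's bias pattern.

    WIT: a stereotype-driven accuracy asymmetry at systole only (better
    weapon identification after black primes, better tool identification
    after white primes), flat at diastole.  FPST: a smaller unarmed-only
    race effect at systole with near-ceiling armed accuracy.  SFIT: a
    phase-invariant prime x object effect (positive black-athletic
    association, no cardiac modulation).  ``phase_effect=False`` removes
    any phase dependence (averaging the two phases' values); the WIT map
    with ``phase_effect=False`` and flat cells doubles as a null.
    """
    task = task_id.lower()
    if task == "wit":
        p = {
            ("black", "weapon", "systole"): 0.90,
            ("black", "tool", "systole"): 0.78,
            ("white", "weapon", "systole"): 0.80,
            ("white", "tool", "systole"): 0.90,
            ("black", "weapon", "diastole"): 0.85,
            ("black", "tool", "diastole"): 0.85,
            ("white", "weapon", "diastole"): 0.85,
            ("white", "tool", "diastole"): 0.85,
        }
    elif task == "fpst":
        p = {
            ("black", "armed", "systole"): 0.92,
            ("white", "armed", "systole"): 0.92,
            ("black", "unarmed", "systole"): 0.80,
            ("white", "unarmed", "systole"): 0.86,
            ("black", "armed", "diastole"): 0.92,
            ("white", "armed", "diastole"): 0.92,
            ("black", "unarmed", "diastole"): 0.84,
            ("white", "unarmed", "diastole"): 0.83,
        }
    elif task == "sfit":
        p = {}
        for ph in PHASES:
            p[("black", "sport", ph)] = 0.88
            p[("white", "sport", ph)] = 0.84
            p[("black", "fruit", ph)] = 0.84
            p[("white", "fruit", ph)] = 0.88
    else:
        raise ValueError(f"unknown task_id: {task_id!r}")
    if phase_effect is False:
        flat = {}
        for (prime, obj, _), _v in p.items():
            mean = (p[(prime, obj, "systole")] + p[(prime, obj, "diastole")]) / 2
            for ph in PHASES:
                flat[(prime, obj, ph)] = mean
        p = flat
    return p


@dataclass(frozen=True)
class BehaviorModelParams:
    """Per-cell Bernoulli accuracy plus a lognormal latency / miss model.

    ``p_correct`` maps each (prime, object, phase) cell to the
    probability of a correct response; ``rt_mean``/``rt_sd`` (ms)
    parameterize the lognormal response latency; ``miss_rate`` is the
    probability of no response at all, independent of latency.
    """

    p_correct: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: default_p_correct("wit")
    )
    miss_rate: float = 0.02
    rt_mean: float = 400.0
    rt_sd: float = 55.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cell, p in self.p_correct.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_correct[{cell}] not in [0, 1]")
        if not 0 <= self.miss_rate <= 1:
            raise ValueError("miss_rate must be in [0, 1]")
        if self.rt_mean <= 0 or self.rt_sd <= 0:
            raise ValueError("rt_mean and rt_sd must be positive")


def generate_rwave_series(
    params: HeartModelParams, n_beats: int, rng: np.random.Generator | None = None
) -> RWaveSeries:
    """Simulate one recording's R-peak times.

    IBIs follow a stationary Gaussian AR(1): innovation SD is scaled so
    the marginal SD equals ``sdnn`` for any ``ar1``.  The optional
    respiratory sinusoid is evaluated at the nominal beat times
    (k * mean_ibi), an adequate approximation for the small modulation
    depths in range.  The first beat is at t = 0.
    """
    if n_beats < 4:
        raise ValueError("n_beats must be >= 4")
    rng = rng or np.random.default_rng(params.seed)
    n_ibi = n_beats - 1
    innov_sd = params.sdnn * np.sqrt(1.0 - params.ar1**2)
    e = rng.normal(0.0, innov_sd, size=n_ibi)
    if n_ibi:
        e[0] = rng.normal(0.0, params.sdnn)  # stationary start
    x = lfilter([1.0], [1.0, -params.ar1], e)
    ibis = params.mean_ibi + x
    if params.rsa_amp > 0:
        k = np.arange(1, n_ibi + 1)
        t_nominal = k * params.mean_ibi / 1000.0  # seconds
        ibis = ibis + params.rsa_amp * np.sin(
            2 * np.pi * params.rsa_freq * t_nominal
        )
    n_clamped = int(np.sum(ibis < IBI_FLOOR_MS))
    ibis = np.maximum(ibis, IBI_FLOOR_MS)
    times = np.concatenate(([0.0], np.cumsum(ibis)))
    realized_sd = float(np.std(ibis, ddof=1)) if n_ibi > 1 else 0.0
    return RWaveSeries(
        times=times,
        meta={
            "clamp_rate": n_clamped / n_ibi if n_ibi else 0.0,
            "realized_mean_ibi": float(np.mean(ibis)) if n_ibi else float("nan"),
            "realized_sdnn": realized_sd,
        },
    )


def generate_trial_sequence(
    design: DesignSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Fully randomized trial order with the design's per-cell counts."""
    cells = design.cells * design.trials_per_cell
    order = rng.permutation(len(cells))
    rows = [cells[i] for i in order]
    df = pd.DataFrame(rows, columns=["prime", "object", "intended_phase"])
    df.insert(0, "trial", np.arange(len(df)))
    return df


def simulate_responses(
    trials: pd.DataFrame,
    design: DesignSpec,
    behavior: BehaviorModelParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw responses, latencies and misses for recoded trials.

    Correctness is Bernoulli in the cell probability keyed on the
    trial's *recoded* (actual) phase — the physiological effect follows
    the heart, not the scheduler — falling back to the intended phase
    for trials landing in the excluded windows.  Latencies are lognormal
    with the requested mean/SD; responses slower than the collection
    window, and outright misses, are recorded as no response.
    """
    out = trials.copy()
    phase = out["recoded_phase"].where(
        out["recoded_phase"].isin(design.phases), out["intended_phase"]
    )
    p = np.array(
        [
            behavior.p_correct[(pr, ob, ph)]
            for pr, ob, ph in zip(out["prime"], out["object"], phase)
        ]
    )
    n = len(out)
    correct_latent = rng.random(n) < p
    sigma2 = np.log1p((behavior.rt_sd / behavior.rt_mean) ** 2)
    mu = np.log(behavior.rt_mean) - sigma2 / 2.0
    rt = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    miss = rng.random(n) < behavior.miss_rate
    responded = ~miss & (rt <= design.collection_window_ms)
    out["rt_ms"] = np.where(responded, rt, np.nan)
    out["responded"] = responded
    out["correct"] = correct_latent & responded
    out["on_time"] = responded & (rt <= design.response_deadline_ms)
    return out


@dataclass(frozen=True)
class SubjectData:
    subject_id: str
    rwaves: RWaveSeries
    trials: pd.DataFrame


@dataclass(frozen=True)
class Cohort:
    design: DesignSpec
    subjects: list[SubjectData]

    @property
    def trials(self) -> pd.DataFrame:
        """All subjects' trial logs, concatenated."""
        df = pd.concat(
            [s.trials.assign(subject_id=s.subject_id) for s in self.subjects],
            ignore_index=True,
        )
        cols = ["subject_id"] + [c for c in df.columns if c != "subject_id"]
        return df[cols]

    def rwave_table(self) -> pd.DataFrame:
        """Two-column (subject_id, r_time_ms) export of every R-peak."""
        return pd.concat(
            [
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "r_time_ms": np.rint(s.rwaves.times).astype(int),
                    }
                )
                for s in self.subjects
            ],
            ignore_index=True,
        )


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def generate_cohort(
    design: DesignSpec,
    heart: HeartModelParams,
    behavior: BehaviorModelParams,
    n_subjects: int,
    gating_params: GatingParams | None = None,
    windows: PhaseWindows | None = None,
) -> Cohort:
    """Simulate a full cohort: heartbeats, gated trials, recoded phases,
    responses.

    Each subject gets an independent heart and behavior stream derived
    deterministically from the two parameter seeds, a randomized trial
    order, a closed-loop gating pass and a-posteriori phase recoding.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (downstream stats need df)")
    gating_params = gating_params or GatingParams(
        min_beats_between_trials=design.min_beats_between_trials
    )
    windows = windows or PhaseWindows()
    heart_seeds = _child_seeds(heart.seed, n_subjects)
    beh_seeds = _child_seeds(behavior.seed, n_subjects)
    # ~5 beats consumed per trial on average; generous margin
    n_beats = design.n_trials * 6 + 16
    subjects = []
    for i in range(n_subjects):
        series = generate_rwave_series(replace(heart, seed=heart_seeds[i]), n_beats)
        rng_b = np.random.default_rng(beh_seeds[i])
        seq = generate_trial_sequence(design, rng_b)
        gated = run_closed_loop(series, seq, gating_params)
        if gated.attrs.get("truncated"):
            raise RuntimeError(
                f"subject {i}: heartbeat stream exhausted during gating"
            )
        recoded = recode_trials(gated, windows)
        full = simulate_responses(recoded, design, behavior, rng_b)
        subjects.append(
            SubjectData(subject_id=f"S{i + 1:03d}", rwaves=series, trials=full)
        )
    return Cohort(design=design, subjects=subjects)


def simulate_cell_accuracies(
    design: DesignSpec,
    behavior: BehaviorModelParams,
    n_subjects: int,
    rng: np.random.Generator,
    return_array: bool = False,
) -> pd.DataFrame | np.ndarray:
    """Sample per-subject per-cell accuracies directly.

    Under ideal gating (no excluded or late trials) a cell's accuracy is
    exactly Binomial(trials_per_cell, p_correct[cell]) / trials_per_cell;
    this samples that marginal distribution without simulating
    heartbeats, which is what large-replicate calibration studies need.
    Returns a long table (subject_id, prime, object, phase, accuracy),
    or with ``return_array=True`` the (n_subjects, 2, 2, 2) array with
    axes ordered (subject, prime, object, phase).
    """
    cells = design.cells
    p = np.array([behavior.p_correct[c] for c in cells])
    counts = rng.binomial(
        design.trials_per_cell, p, size=(n_subjects, len(cells))
    )
    acc = counts / design.trials_per_cell
    if return_array:
        return acc.reshape(n_subjects, 2, 2, 2)
    rows = []
    for s in range(n_subjects):
        for j, (pr, ob, ph) in enumerate(cells):
            rows.append((f"S{s + 1:03d}", pr, ob, ph, acc[s, j]))
    return pd.DataFrame(
        rows, columns=["subject_id", "prime", "object", "phase", "accuracy"]
    )


def synthesize_ecg_trace(
    r_times: np.ndarray,
    sample_period_ms: float = 1.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Toy impulse-train 'ECG' for exercising the threshold detector.

    One supra-threshold sample per R-wave on a flat baseline plus
    optional Gaussian noise; no P/QRS/T morphology is modelled.
    """
    r = np.asarray(r_times, dtype=float)
    n = int(np.floor(r.max() / sample_period_ms)) + 2 if r.size else 1
    trace = np.zeros(n)
    idx = np.rint(r / sample_period_ms).astype(int)
    trace[idx] = amplitude
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        noise = rng.normal(0.0, noise_sd, size=n)
        trace = trace + np.where(trace == 0, noise, 0.0)
    return trace
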