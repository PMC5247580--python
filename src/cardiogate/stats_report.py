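"""Within-subject inference: repeated-measures ANOVA, planned paired
contrasts, Newman-Keuls correction, and the pipeline orchestrator.

The factorial designs here are fully within-subject with two-level
factors, so every effect has one numerator degree of freedom, is tested
against its own subject-by-effect interaction error term, and its F
equals the squared paired t of the corresponding difference contrast.
Sphericity corrections are unnecessary with two-level factors (the
assumption is trivially satisfied), so none are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior_metrics as bm
from .gating import GatingParams
from .phase_recode import (
    PhaseWindows,
    cumulative_onset_histogram,
    exclusion_report,
)
from .synthetic_data import (
    BehaviorModelParams,
    Cohort,
    DesignSpec,
    HeartModelParams,
    _child_seeds,
    default_p_correct,
    generate_cohort,
)

__all__ = [
    "rm_anova_within",
    "rm_anova_2x2x2",
    "ContrastResult",
    "paired_t",
    "newman_keuls",
    "newman_keuls_pairs",
    "prime_contrasts",
    "PipelineReport",
    "run_pipeline",
    "write_report",
]


# ---------------------------------------------------------------- ANOVA


def _effect_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Sum of squares for the marginal effect spanned by ``axes``.

    Inclusion-exclusion over marginal means: the effect term at each
    level combination is the alternating sum of the means over every
    subset of the axes, and the SS scales the squared terms by the
    number of observations per level combination.
    """
    term = np.zeros((1,) * y.ndim)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            mean_axes = tuple(ax for ax in range(y.ndim) if ax not in sub)
            m = y.mean(axis=mean_axes, keepdims=True) if mean_axes else y
            term = term + (-1.0) ** (len(axes) - len(sub)) * m
    return float(np.sum(term**2) * (y.size / term.size))


def rm_anova_within(y: np.ndarray, factor_names: list[str]) -> pd.DataFrame:
    """Fully within-subject ANOVA on a (subjects x levels...) array.

    ``y[s, i, j, ...]`` holds subject s's value in the cell with factor
    levels (i, j, ...).  Every effect (each non-empty factor subset) is
    tested against its own interaction with subjects.  Returns one row
    per effect with SS_effect, SS_error, df columns, F, p and partial
    eta squared.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != len(factor_names) + 1:
        raise ValueError("factor_names must match the non-subject dimensions")
    if np.isnan(y).any():
        raise ValueError("missing cells in the subject x cell matrix")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    factor_axes = range(1, y.ndim)
    for r in range(1, len(factor_names) + 1):
        for axes in combinations(factor_axes, r):
            name = ":".join(factor_names[a - 1] for a in axes)
            ss_eff = _effect_ss(y, axes)
            ss_err = _effect_ss(y, (0, *axes))
            df_eff = int(np.prod([y.shape[a] - 1 for a in axes]))
            df_err = (n - 1) * df_eff
            ms_eff, ms_err = ss_eff / df_eff, ss_err / df_err
            F = ms_eff / ms_err if ms_err > 0 else np.inf
            p = float(stats.f.sf(F, df_eff, df_err))
            rows.append(
                {
                    "effect": name,
                    "SS_effect": ss_eff,
                    "SS_error": ss_err,
                    "df_effect": df_eff,
                    "df_error": df_err,
                    "F": F,
                    "p": p,
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err)
                    if ss_eff + ss_err > 0
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


def rm_anova_2x2x2(
    data: pd.DataFrame,
    dv: str = "accuracy",
    subject: str = "subject_id",
    within: list[str] | None = None,
) -> pd.DataFrame:
    """Three-way fully within-subject ANOVA from a long table.

    ``within`` defaults to ``["prime", "object", "phase"]``.  Every
    subject must contribute a complete set of cells; subjects with
    missing cells are reported by id.
    """
    within = within or ["prime", "object", "phase"]
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="first"
    )
    full = pd.MultiIndex.from_product(
        [sorted(data[w].unique()) for w in within], names=within
    )
    wide = wide.reindex(columns=full)
    bad = wide.index[wide.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"subjects with missing cells: {bad}")
    shape = (len(wide),) + tuple(len(lv) for lv in full.levels)
    y = wide.to_numpy().reshape(shape)
    return rm_anova_within(y, within)


# ------------------------------------------------------------ contrasts


@dataclass
class ContrastResult:
    """One planned paired comparison."""

    label: str
    mean_diff: float
    t: float
    df: int
    p_two_tailed: float
    cohen_d: float
    corrected_p: float | None = None
    degenerate: bool = field(default=False)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_diff": self.mean_diff,
            "t": self.t,
            "df": self.df,
            "p_two_tailed": self.p_two_tailed,
            "cohen_d": self.cohen_d,
            "corrected_p": self.corrected_p,
        }


def paired_t(diffs: np.ndarray, label: str = "") -> ContrastResult:
    """Classic paired t-test on per-subject difference scores.

    Cohen's d for paired data: mean difference / SD of differences.
    A zero-variance difference vector is flagged rather than silently
    propagated: all-zero differences give t = 0, p = 1, d = 0; a
    constant non-zero difference gives an infinite t.
    """
    d = np.asarray(diffs, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    m = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if m == 0.0:
            return ContrastResult(label, 0.0, 0.0, n - 1, 1.0, 0.0,
                                  degenerate=True)
        warnings.warn(
            f"contrast {label!r}: zero variance of differences (t infinite)",
            stacklevel=2,
        )
        t = float(np.sign(m) * np.inf)
        return ContrastResult(label, m, t, n - 1, 0.0, t, degenerate=True)
    t = m / (sd / np.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), n - 1))
    return ContrastResult(label, m, float(t), n - 1, p, m / sd)


def newman_keuls(
    means: pd.Series, ms_error: float, df_error: int, n: int
) -> pd.DataFrame:
    """Stepwise Newman-Keuls studentized-range correction.

    Means are rank ordered; a comparison spanning ``r`` ordered means is
    referred to the studentized range with ``r`` groups, and a
    comparison contained in a non-significant wider range inherits that
    range's (larger) p — implemented by taking the maximum p over all
    containing ranges.  ``n`` is the per-mean sample size; ``ms_error``
    the pooled within-subject error mean square.  For two means the
    procedure reduces to a single range test with q = t * sqrt(2).
    """
    if n <= 1:
        raise ValueError("n must exceed 1")
    if len(means) < 2:
        raise ValueError("need at least 2 means")
    if ms_error < 0 or df_error < 1:
        raise ValueError("invalid error term")
    m = pd.Series(means).sort_values()
    k = len(m)
    se = np.sqrt(ms_error / n)
    praw = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            span = j - i + 1
            q = (m.iloc[j] - m.iloc[i]) / se if se > 0 else np.inf
            praw[i, j] = float(stats.studentized_range.sf(q, span, df_error))
    pcorr = praw.copy()
    # widest spans first; each comparison inherits the max p of any
    # containing range (the stepwise stopping rule)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            containing = []
            if i > 0:
                containing.append(pcorr[i - 1, j])
            if j < k - 1:
                containing.append(pcorr[i, j + 1])
            if containing:
                pcorr[i, j] = max(pcorr[i, j], *containing)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "level_lo": m.index[i],
                    "level_hi": m.index[j],
                    "mean_lo": m.iloc[i],
                    "mean_hi": m.iloc[j],
                    "span": j - i + 1,
                    "q": (m.iloc[j] - m.iloc[i]) / se if se > 0 else np.inf,
                    "p_raw": praw[i, j],
                    "p_corrected": min(pcorr[i, j], 1.0),
                }
            )
    return pd.DataFrame(rows)


def newman_keuls_pairs(wide: pd.DataFrame) -> pd.DataFrame:
    """Newman-Keuls over the columns of a subjects x conditions table.

    The error term is the pooled within-subject mean square from the
    one-way repeated-measures ANOVA of the conditions entering the
    comparison (error df = (n - 1)(k - 1)).
    """
    y = wide.to_numpy(dtype=float)
    n, k = y.shape
    resid = y - y.mean(0, keepdims=True) - y.mean(1, keepdims=True) + y.mean()
    df_err = (n - 1) * (k - 1)
    ms_err = float(np.sum(resid**2) / df_err)
    means = pd.Series(y.mean(0), index=wide.columns)
    return newman_keuls(means, ms_err, df_err, n)


def prime_contrasts(acc: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Planned black-vs-white accuracy contrasts per object and phase,
    with Newman-Keuls corrected p values over the full set of cell means.
    """
    wide = acc.pivot_table(
        index="subject_id",
        columns=["prime", "object", "phase"],
        values="accuracy",
        aggfunc="first",
    )
    if wide.isna().any().any():
        raise ValueError("missing cells; cannot form planned contrasts")
    flat = wide.copy()
    flat.columns = ["_".join(c) for c in wide.columns]
    nk = newman_keuls_pairs(flat)
    results = []
    for obj in design.objects:
        for phase in design.phases:
            a = wide[("black", obj, phase)].to_numpy()
            b = wide[("white", obj, phase)].to_numpy()
            res = paired_t(a - b, label=f"{obj}@{phase}: black - white")
            ca, cb = f"black_{obj}_{phase}", f"white_{obj}_{phase}"
            hit = nk[
                ((nk["level_lo"] == ca) & (nk["level_hi"] == cb))
                | ((nk["level_lo"] == cb) & (nk["level_hi"] == ca))
            ]
            if len(hit):
                res.corrected_p = float(
                    max(hit["p_corrected"].iloc[0], res.p_two_tailed)
                )
            results.append(res.as_dict())
    return pd.DataFrame(results)


# -------------------------------------------------------------- pipeline


@dataclass
class PipelineReport:
    """Everything one simulated study produces."""

    design: DesignSpec
    config: dict
    trials: pd.DataFrame
    rwaves: pd.DataFrame
    exclusions: pd.DataFrame
    onset_histogram: pd.DataFrame
    accuracy: pd.DataFrame
    cell_means: pd.DataFrame
    sdt: pd.DataFrame
    pdp: pd.DataFrame
    anova_accuracy: pd.DataFrame
    anova_d_prime: pd.DataFrame
    anova_criterion: pd.DataFrame
    anova_pdp_control: pd.DataFrame
    anova_pdp_automatic: pd.DataFrame
    contrasts: pd.DataFrame
    points: pd.DataFrame | None
    log: list[str]


def _build_params(config: dict):
    study = config.get("study", "wit")
    design = DesignSpec.from_task_id(study, **config.get("design", {}))
    seed = int(config.get("seed", 0))
    heart_seed, beh_seed = _child_seeds(seed, 2)
    heart_cfg = dict(config.get("heart", {}))
    heart_cfg.setdefault("seed", heart_seed)
    heart = HeartModelParams(**heart_cfg)
    beh_cfg = dict(config.get("behavior", {}))
    beh_cfg.setdefault("seed", beh_seed)
    if "p_correct" in beh_cfg:
        beh_cfg["p_correct"] = {
            tuple(k.split("_")): float(v) for k, v in beh_cfg["p_correct"].items()
        }
    else:
        beh_cfg["p_correct"] = default_p_correct(study)
    behavior = BehaviorModelParams(**beh_cfg)
    gate_cfg = dict(config.get("gating", {}))
    gate_cfg.setdefault("min_beats_between_trials", design.min_beats_between_trials)
    gating = GatingParams(**gate_cfg)
    win_cfg = config.get("windows", {})
    windows = PhaseWindows(
        **{k: tuple(v) for k, v in win_cfg.items()}
    ) if win_cfg else PhaseWindows()
    n_subjects = int(config.get("n_subjects", 30))
    return design, heart, behavior, gating, windows, n_subjects


def run_pipeline(config: dict) -> PipelineReport:
    """Simulate a cohort and run the full analysis chain.

    Stages: cohort simulation (heartbeats, gated trials, recoded phases,
    responses) -> exclusion accounting and cumulative onset curves ->
    per-cell accuracy, SDT and PDP indices (+ FPST points) -> within-
    subject ANOVAs and planned prime contrasts with Newman-Keuls
    correction.  Deterministic for a given config (including seed).
    """
    design, heart, behavior, gating, windows, n_subjects = _build_params(config)
    log = [f"study={design.task_id} n_subjects={n_subjects} seed={config.get('seed', 0)}"]
    cohort = generate_cohort(design, heart, behavior, n_subjects, gating, windows)
    trials = cohort.trials
    log.append(f"simulate: {len(trials)} trials over {n_subjects} subjects")

    excl = exclusion_report(trials)
    pooled = float(excl.loc[excl["subject_id"] == "POOLED", "rate"].iloc[0])
    log.append(f"recode: pooled exclusion rate {pooled:.4f}")
    hist = cumulative_onset_histogram(trials, bin_ms=10.0)

    acc = bm.accuracy_table(trials, design)
    n_missing = int(acc["accuracy"].isna().sum())
    if n_missing:
        log.append(f"metrics: {n_missing} empty subject x cell accuracies (NaN)")
    cell_means = (
        acc.groupby(["prime", "object", "phase"])["accuracy"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(v.notna().sum()))
        .reset_index()
    )
    sdt = bm.sdt_table(acc, design)
    pdp = bm.pdp_table(acc, design)
    points = bm.fpst_points(trials, design) if design.payoff else None

    anova_acc = rm_anova_2x2x2(acc)

    def _two_way(df: pd.DataFrame, dv: str) -> pd.DataFrame:
        # a subject with an undefined index (e.g. PDP automatic when
        # control = 1) is dropped from that ANOVA, not imputed
        ok = df.groupby("subject_id")[dv].transform(lambda v: v.notna().all())
        dropped = sorted(df.loc[~ok, "subject_id"].unique())
        if dropped:
            log.append(f"stats[{dv}]: dropped subjects with undefined values: {dropped}")
        if df.loc[ok, "subject_id"].nunique() < 2:
            log.append(f"stats[{dv}]: fewer than 2 complete subjects; ANOVA skipped")
            return pd.DataFrame(
                columns=["effect", "SS_effect", "SS_error", "df_effect",
                         "df_error", "F", "p", "partial_eta_sq"]
            )
        return rm_anova_2x2x2(df[ok], dv=dv, within=["prime", "phase"])

    anova_d = _two_way(sdt, "d_prime")
    anova_c = _two_way(sdt, "criterion_c")
    anova_ctrl = _two_way(pdp, "control")
    anova_auto = _two_way(pdp, "automatic")
    contrasts = prime_contrasts(acc, design)
    three_way = anova_acc.loc[anova_acc["effect"] == "prime:object:phase"]
    log.append(
        "stats: three-way F(%d,%d)=%.2f p=%.3f"
        % (
            int(three_way["df_effect"].iloc[0]),
            int(three_way["df_error"].iloc[0]),
            float(three_way["F"].iloc[0]),
            float(three_way["p"].iloc[0]),
        )
    )
    return PipelineReport(
        design=design,
        config=config,
        trials=trials,
        rwaves=cohort.rwave_table(),
        exclusions=excl,
        onset_histogram=hist,
        accuracy=acc,
        cell_means=cell_means,
        sdt=sdt,
        pdp=pdp,
        anova_accuracy=anova_acc,
        anova_d_prime=anova_d,
        anova_criterion=anova_c,
        anova_pdp_control=anova_ctrl,
        anova_pdp_automatic=anova_auto,
        contrasts=contrasts,
        points=points,
        log=log,
    )


def write_report(report: PipelineReport, outdir, plots: bool = False) -> None:
    """Write every report table (and optionally figures) to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "trials.csv": report.trials,
        "rwaves.csv": report.rwaves,
        "exclusions.csv": report.exclusions,
        "onset_histogram.csv": report.onset_histogram,
        "accuracy.csv": report.accuracy,
        "cell_means.csv": report.cell_means,
        "sdt.csv": report.sdt,
        "pdp.csv": report.pdp,
        "anova_accuracy.csv": report.anova_accuracy,
        "anova_d_prime.csv": report.anova_d_prime,
        "anova_criterion.csv": report.anova_criterion,
        "anova_pdp_control.csv": report.anova_pdp_control,
        "anova_pdp_automatic.csv": report.anova_pdp_automatic,
        "contrasts.csv": report.contrasts,
    }
    if report.points is not None:
        tables["points.csv"] = report.points
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    (out / "run.log").write_text("\n".join(report.log) + "\n")
    if plots:
        from .plots import plot_condition_means, plot_cumulative_onsets

        plot_cumulative_onsets(
            report.onset_histogram, out / "cumulative_onsets.png"
        )
        plot_condition_means(report.cell_means, out / "condition_means.png")
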