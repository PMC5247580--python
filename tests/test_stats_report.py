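import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cardiogate as cg
from _oracles import brute_rm_anova

TOY = np.array(
    [
        [[[0, 7], [6, 4]], [[4, 8], [0, 6]]],
        [[[2, 0], [5, 9]], [[7, 7], [7, 7]]],
        [[[5, 1], [8, 4]], [[5, 3], [1, 9]]],
        [[[7, 6], [4, 8]], [[5, 4], [4, 2]]],
    ],
    dtype=float,
)

# frozen from the brute-force sums-of-squares oracle on TOY
TOY_F = {
    "A": 0.0278063851699,
    "B": 0.664482306684,
    "P": 0.954738330976,
    "A:B": 8.71314741036,
    "A:P": 0.393282773564,
    "B:P": 0.79842519685,
    "A:B:P": 0.222731439047,
}


class TestRmAnova:
    def test_toy_matrix_matches_frozen_oracle_values(self):
        res = cg.rm_anova_within(TOY, ["A", "B", "P"]).set_index("effect")
        for effect, F in TOY_F.items():
            assert res.loc[effect, "F"] == pytest.approx(F, rel=1e-10)

    def test_matches_live_brute_force_oracle(self, rng):
        y = rng.normal(size=(7, 2, 2, 2))
        res = cg.rm_anova_within(y, ["A", "B", "P"]).set_index("effect")
        oracle = brute_rm_anova(y)
        remap = {"A": "A", "B": "B", "C": "P", "AB": "A:B", "AC": "A:P",
                 "BC": "B:P", "ABC": "A:B:P"}
        for okey, ekey in remap.items():
            ss_eff, ss_err, F, p = oracle[okey]
            assert res.loc[ekey, "SS_effect"] == pytest.approx(ss_eff, rel=1e-10)
            assert res.loc[ekey, "SS_error"] == pytest.approx(ss_err, rel=1e-10)
            assert res.loc[ekey, "F"] == pytest.approx(F, rel=1e-10)
            assert res.loc[ekey, "p"] == pytest.approx(p, rel=1e-9)

    def test_matches_statsmodels_anova_rm(self, rng):
        from statsmodels.stats.anova import AnovaRM

        y = rng.normal(size=(8, 2, 2, 2))
        res = cg.rm_anova_within(y, ["A", "B", "P"]).set_index("effect")
        rows = [
            (s, str(a), str(b), str(p), y[s, a, b, p])
            for s in range(8)
            for a in range(2)
            for b in range(2)
            for p in range(2)
        ]
        long = pd.DataFrame(rows, columns=["subj", "A", "B", "P", "v"])
        sm = AnovaRM(long, "v", "subj", within=["A", "B", "P"]).fit().anova_table
        for sm_name, name in [
            ("A", "A"), ("B", "B"), ("P", "P"),
            ("A:B", "A:B"), ("A:P", "A:P"), ("B:P", "B:P"),
            ("A:B:P", "A:B:P"),
        ]:
            assert res.loc[name, "F"] == pytest.approx(
                sm.loc[sm_name, "F Value"], rel=1e-8
            )
            assert res.loc[name, "p"] == pytest.approx(
                sm.loc[sm_name, "Pr > F"], rel=1e-6
            )

    def test_pure_subject_offsets_give_zero_effect_ss(self):
        offsets = np.array([1.0, 5.0, -2.0, 0.3])
        y = np.broadcast_to(offsets[:, None, None, None], (4, 2, 2, 2)).copy()
        res = cg.rm_anova_within(y, ["A", "B", "P"])
        assert np.allclose(res["SS_effect"], 0.0, atol=1e-12)

    def test_f_equals_squared_paired_t_for_each_effect(self, rng):
        y = rng.normal(size=(10, 2, 2, 2))
        res = cg.rm_anova_within(y, ["A", "B", "P"]).set_index("effect")
        signs = {0: np.array([1.0, 1.0]), 1: np.array([1.0, -1.0])}
        for mask, name in [
            ((1, 0, 0), "A"), ((0, 1, 0), "B"), ((0, 0, 1), "P"),
            ((1, 1, 0), "A:B"), ((1, 0, 1), "A:P"), ((0, 1, 1), "B:P"),
            ((1, 1, 1), "A:B:P"),
        ]:
            w = (
                signs[mask[0]][:, None, None]
                * signs[mask[1]][None, :, None]
                * signs[mask[2]][None, None, :]
            )
            L = (y * w).sum(axis=(1, 2, 3))
            t = cg.paired_t(L)
            assert res.loc[name, "F"] == pytest.approx(t.t**2, rel=1e-9)
            assert res.loc[name, "p"] == pytest.approx(t.p_two_tailed, rel=1e-9)

    def test_partial_eta_sq_definition(self, rng):
        y = rng.normal(size=(6, 2, 2, 2))
        res = cg.rm_anova_within(y, ["A", "B", "P"])
        eta = res["SS_effect"] / (res["SS_effect"] + res["SS_error"])
        assert np.allclose(res["partial_eta_sq"], eta)
        assert ((res["partial_eta_sq"] >= 0) & (res["partial_eta_sq"] <= 1)).all()

    def test_missing_cell_reports_subject(self):
        df = pd.DataFrame(
            {
                "subject_id": ["S1"] * 8 + ["S2"] * 8,
                "prime": (["black"] * 4 + ["white"] * 4) * 2,
                "object": ["tool", "tool", "weapon", "weapon"] * 4,
                "phase": ["systole", "diastole"] * 8,
                "accuracy": np.linspace(0.5, 1.0, 16),
            }
        ).iloc[:15]  # S2 loses one cell
        with pytest.raises(ValueError, match="S2"):
            cg.rm_anova_2x2x2(df)

    def test_long_format_matches_array_path(self, small_cohort):
        acc = cg.accuracy_table(small_cohort.trials, small_cohort.design)
        res = cg.rm_anova_2x2x2(acc)
        assert set(res["effect"]) == {
            "prime", "object", "phase", "prime:object", "prime:phase",
            "object:phase", "prime:object:phase",
        }
        assert (res["df_error"] == 3).all()


class TestPairedT:
    def test_all_zero_differences(self):
        res = cg.paired_t(np.zeros(8))
        assert (res.t, res.p_two_tailed, res.cohen_d) == (0.0, 1.0, 0.0)
        assert res.degenerate

    def test_hand_arithmetic(self):
        res = cg.paired_t(np.array([1.0, 2.0, 3.0, 4.0]))
        assert res.mean_diff == pytest.approx(2.5)
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.cohen_d == pytest.approx(1.936, abs=1e-3)
        assert res.df == 3

    def test_sign_flip_antisymmetry(self, rng):
        d = rng.normal(0.3, 1.0, 12)
        a, b = cg.paired_t(d), cg.paired_t(-d)
        assert b.t == pytest.approx(-a.t)
        assert b.cohen_d == pytest.approx(-a.cohen_d)
        assert b.p_two_tailed == pytest.approx(a.p_two_tailed)

    def test_constant_nonzero_differences_flagged_infinite(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = cg.paired_t(np.full(5, 0.2))
        assert np.isinf(res.t) and res.t > 0

    def test_matches_scipy(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        res = cg.paired_t(a - b)
        t, p = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(t)
        assert res.p_two_tailed == pytest.approx(p)

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            cg.paired_t([1.0])


class TestNewmanKeuls:
    def test_two_means_reduce_to_paired_t(self, rng):
        wide = pd.DataFrame(
            {"a": rng.normal(0, 1, 12), "b": rng.normal(0.8, 1, 12)}
        )
        nk = cg.newman_keuls_pairs(wide)
        t = cg.paired_t(wide["b"] - wide["a"])
        assert nk["q"].iloc[0] == pytest.approx(abs(t.t) * np.sqrt(2), rel=1e-9)
        assert nk["p_corrected"].iloc[0] == pytest.approx(t.p_two_tailed, rel=1e-6)

    def test_corrected_p_monotone_in_raw_p(self, rng):
        wide = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
        nk = cg.newman_keuls_pairs(wide)
        assert (nk["p_corrected"] >= nk["p_raw"] - 1e-12).all()
        assert ((nk["p_corrected"] >= 0) & (nk["p_corrected"] <= 1)).all()

    def test_containment_inheritance(self, rng):
        wide = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        nk = cg.newman_keuls_pairs(wide).set_index(["level_lo", "level_hi"])
        order = nk.reset_index().sort_values("mean_lo")
        # the widest span's corrected p lower-bounds every contained pair
        widest = nk[nk["span"] == 4]["p_corrected"].iloc[0]
        assert (nk["p_corrected"] >= widest - 1e-12).all()

    def test_familywise_error_near_nominal_under_null(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 800
        for _ in range(reps):
            wide = pd.DataFrame(rng.normal(size=(10, 4)))
            nk = cg.newman_keuls_pairs(wide)
            hits += (nk["p_corrected"] < 0.05).any()
        rate = hits / reps
        assert 0.02 < rate < 0.09

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cg.newman_keuls(pd.Series([1.0, 2.0]), 1.0, 10, n=1)
        with pytest.raises(ValueError):
            cg.newman_keuls(pd.Series([1.0]), 1.0, 10, n=5)


class TestPipeline:
    CFG = {
        "study": "wit",
        "n_subjects": 5,
        "seed": 8,
        "design": {"trials_per_cell": 8},
        "behavior": {"miss_rate": 0.0, "rt_mean": 300, "rt_sd": 15},
    }

    def test_report_complete_and_deterministic(self):
        r1 = cg.run_pipeline(dict(self.CFG))
        r2 = cg.run_pipeline(dict(self.CFG))
        pd.testing.assert_frame_equal(r1.trials, r2.trials)
        pd.testing.assert_frame_equal(r1.anova_accuracy, r2.anova_accuracy)
        assert len(r1.accuracy) == 5 * 8
        assert len(r1.cell_means) == 8
        assert len(r1.contrasts) == 4
        assert r1.points is None
        assert any("exclusion" in line for line in r1.log)

    def test_fpst_pipeline_reports_points(self):
        cfg = dict(self.CFG, study="fpst", design={"trials_per_cell": 6})
        rep = cg.run_pipeline(cfg)
        assert rep.points is not None
        assert len(rep.points) == 5
        assert rep.design.payoff is not None

    def test_sfit_pipeline_runs(self):
        cfg = dict(self.CFG, study="sfit", design={"trials_per_cell": 6})
        rep = cg.run_pipeline(cfg)
        assert set(rep.accuracy["object"]) <= {"fruit", "sport"}

    def test_write_report(self, tmp_path):
        rep = cg.run_pipeline(dict(self.CFG))
        cg.write_report(rep, tmp_path)
        for name in ("trials.csv", "accuracy.csv", "anova_accuracy.csv",
                     "contrasts.csv", "exclusions.csv", "run.log"):
            assert (tmp_path / name).exists()

    def test_custom_p_correct_from_flat_keys(self):
        cfg = dict(self.CFG)
        cfg["behavior"] = {
            "miss_rate": 0.0,
            "rt_mean": 300,
            "rt_sd": 15,
            "p_correct": {
                f"{p}_{o}_{ph}": 0.9
                for p in ("black", "white")
                for o in ("tool", "weapon")
                for ph in ("systole", "diastole")
            },
        }
        rep = cg.run_pipeline(cfg)
        assert rep.accuracy["accuracy"].mean() > 0.75
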