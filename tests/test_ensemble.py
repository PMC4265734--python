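"""Exhaustive-subset ensemble: enumeration, balanced/matched resampling,
stratified splitting, early-stopping training, contributions and ranking."""

import numpy as np
import pandas as pd
import pytest

import oagsim as og
from oagsim.ensemble import MatchingError, _part_sizes


def panel_of(k):
    return og.VariablePanel(clinical=tuple(f"v{i}" for i in range(k)))


class TestEnumerateSubsets:
    @pytest.mark.parametrize("k,expected", [(1, 1), (3, 7), (14, 16_383)])
    def test_subset_counts(self, k, expected):
        assert len(og.enumerate_subsets(panel_of(k))) == expected

    @pytest.mark.parametrize("k", range(1, 17))
    def test_count_is_two_to_k_minus_one(self, k):
        masks = og.enumerate_subsets(panel_of(k))
        assert len(masks) == 2 ** k - 1
        assert masks[0] == 1 and masks[-1] == 2 ** k - 1  # ascending, no empty

    def test_guard_against_explosion(self):
        with pytest.raises(ValueError):
            panel_of(21)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            og.VariablePanel(clinical=("age",), snps=("age",))


class TestBalancedSampling:
    def test_unmatched_counts(self, retro_cohort):
        cases = retro_cohort[retro_cohort["status"] == 1]
        ctrls = retro_cohort[retro_cohort["status"] == 0]
        out = og.sample_balanced_cohort(cases, ctrls, seed=1)
        assert len(out) == 134
        assert out["status"].sum() == 67
        # sampling without replacement: all picked controls distinct
        assert out["pid"].nunique() == 134

    def test_matched_within_tolerance(self, retro_cohort):
        cases = retro_cohort[retro_cohort["status"] == 1]
        ctrls = retro_cohort[retro_cohort["status"] == 0]
        out = og.sample_balanced_cohort(cases, ctrls, age_matched=True,
                                        tolerance_years=2.0, seed=2)
        got_cases = out[out["status"] == 1].sort_values("pid")
        assert len(out) == 134
        # re-derive the matching bound: every control within 2y of some case
        case_ages = np.sort(got_cases["age"].to_numpy())
        for a in out.loc[out["status"] == 0, "age"]:
            assert np.min(np.abs(case_ages - a)) <= 2.0 + 1e-9

    def test_infeasible_matching_errors(self):
        cases = pd.DataFrame({"status": 1, "age": [70.0, 71.0], "x": 0.0})
        ctrls = pd.DataFrame({"status": 0, "age": [30.0] * 5, "x": 0.0})
        with pytest.raises(MatchingError, match="70"):
            og.sample_balanced_cohort(cases, ctrls, age_matched=True,
                                      tolerance_years=2.0, seed=3)

    def test_more_cases_than_controls_errors(self):
        cases = pd.DataFrame({"status": 1, "age": [70.0, 71.0, 72.0]})
        ctrls = pd.DataFrame({"status": 0, "age": [70.0]})
        with pytest.raises(ValueError):
            og.sample_balanced_cohort(cases, ctrls, seed=0)


class TestSplit:
    def test_134_rows_split_94_20_20(self):
        rows = pd.DataFrame({"status": [0, 1] * 67,
                             "x": np.arange(134, dtype=float)})
        tr, va, te = og.split_train_val_test(rows, seed=4)
        assert (len(tr), len(va), len(te)) == (94, 20, 20)

    def test_disjoint_and_exhaustive(self):
        rows = pd.DataFrame({"status": [0, 1] * 67,
                             "x": np.arange(134, dtype=float)})
        tr, va, te = og.split_train_val_test(rows, seed=5)
        ids = pd.concat([tr, va, te])["x"]
        assert sorted(ids) == sorted(rows["x"])
        assert ids.nunique() == len(rows)

    def test_stratified_half_cases(self):
        rows = pd.DataFrame({"status": [0, 1] * 67,
                             "x": np.arange(134, dtype=float)})
        for part in og.split_train_val_test(rows, seed=6):
            assert abs(part["status"].sum() - len(part) / 2) <= 1

    def test_remainder_goes_train_first(self):
        assert _part_sizes(134, (0.70, 0.15, 0.15)) == [94, 20, 20]
        assert _part_sizes(10, (0.70, 0.15, 0.15)) == [8, 1, 1]

    def test_single_class_part_errors(self):
        rows = pd.DataFrame({"status": [1] * 50, "x": np.arange(50.0)})
        with pytest.raises(ValueError):
            og.split_train_val_test(rows, seed=7)


class TestTraining:
    def test_separable_data_reaches_zero_validation_error(self):
        rng = np.random.default_rng(11)
        n = 120
        df = pd.DataFrame({"status": np.repeat([0, 1], n // 2)})
        df["x"] = df["status"] * 4.0 + rng.normal(0, 0.2, n)
        tr, va, te = og.split_train_val_test(df, seed=8)
        net = og.train_classifier(tr, va, ["x"], seed=9)
        assert net.best_val_error_ == 0.0
        assert og.error_score(net, te) == 0.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(12)
        errs = []
        for s in range(8):
            n = 200
            df = pd.DataFrame({"status": np.repeat([0, 1], n // 2),
                               "x": rng.normal(size=n),
                               "z": rng.normal(size=n)})
            tr, va, te = og.split_train_val_test(df, seed=s)
            net = og.train_classifier(tr, va, ["x", "z"], seed=s)
            errs.append(og.error_score(net, te))
        assert 0.35 < np.mean(errs) < 0.65

    def test_same_seed_identical_predictions(self, planted):
        cases, ctrls = planted
        cohort = og.sample_balanced_cohort(cases, ctrls, seed=13)
        tr, va, te = og.split_train_val_test(cohort, seed=14)
        a = og.train_classifier(tr, va, ["signal", "noise0"], seed=15)
        b = og.train_classifier(tr, va, ["signal", "noise0"], seed=15)
        X = te[["signal", "noise0"]].to_numpy()
        assert np.array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_error_score_arithmetic(self):
        class Stub:
            input_variables_ = ["x"]

            def predict(self, X):
                return np.zeros(len(X), dtype=int)

        test = pd.DataFrame({"status": [1, 1, 1, 0] * 5, "x": 0.0})
        assert og.error_score(Stub(), test) == pytest.approx(15 / 20)


class TestRunEnsemble:
    def test_small_sweep_counts_and_range(self, planted):
        cases, ctrls = planted
        panel = og.VariablePanel(clinical=("signal", "noise0", "noise1"))
        runs = og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=16)
        assert len(runs) == 14  # 7 subsets x 2 reps
        assert runs["error"].between(0, 1).all()

    def test_rerun_reproduces_error_scores(self, planted):
        cases, ctrls = planted
        panel = og.VariablePanel(clinical=("signal", "noise0", "noise1"))
        a = og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=17)
        b = og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=17)
        pd.testing.assert_frame_equal(a, b)

    def test_checkpoint_resume(self, planted, tmp_path):
        cases, ctrls = planted
        panel = og.VariablePanel(clinical=("signal", "noise0"))
        ck = tmp_path / "runs.tsv"
        full = og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=18)
        # first pass: only one subset, checkpointed
        og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=18,
                        subset_cap=1, checkpoint=str(ck))
        resumed = og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=18,
                                  checkpoint=str(ck))
        pd.testing.assert_frame_equal(
            resumed.sort_values(["subset", "rep"]).reset_index(drop=True),
            full.sort_values(["subset", "rep"]).reset_index(drop=True))

    def test_subset_cap_limits_runs(self, planted):
        cases, ctrls = planted
        panel = og.VariablePanel(clinical=("signal", "noise0", "noise1"))
        runs = og.run_ensemble(cases, ctrls, panel, reps=3, master_seed=19,
                               subset_cap=4)
        assert len(runs) == 12
        assert set(runs["subset"]) == {1, 2, 3, 4}


class TestContributions:
    def test_constant_errors_zero_contribution(self):
        panel = panel_of(3)
        masks = og.enumerate_subsets(panel)
        runs = pd.DataFrame({"subset": np.repeat(masks, 2),
                             "rep": [1, 2] * len(masks),
                             "error": 0.25})
        for v in panel.names:
            assert og.variable_contribution(runs, panel, v) == pytest.approx(0.0)

    def test_pairing_count_matches_counting_oracle(self):
        # every subset S omitting v pairs with S|v: 2^(k-1)-1 pairs (S nonempty)
        for k in (2, 3, 5):
            panel = panel_of(k)
            masks = og.enumerate_subsets(panel)
            for i, v in enumerate(panel.names):
                bit = 1 << i
                pairs = [(m, m | bit) for m in masks if not m & bit]
                assert len(pairs) == 2 ** (k - 1) - 1

    def test_paired_estimator_equals_hand_average(self):
        panel = panel_of(2)
        runs = pd.DataFrame({"subset": [1, 2, 3], "rep": 1,
                             "error": [0.4, 0.5, 0.3]})
        # for v0 (bit 1): only pair is ({v1}, {v1,v0}): 0.5 - 0.3 = 0.2
        assert og.variable_contribution(runs, panel, "v0") == pytest.approx(0.2)
        # marginal: mean(without v0)=0.5, mean(with)=0.35
        assert og.variable_contribution(runs, panel, "v0",
                                        estimator="marginal") == pytest.approx(0.15)

    def test_unknown_variable_errors(self):
        panel = panel_of(2)
        runs = pd.DataFrame({"subset": [1], "rep": [1], "error": [0.5]})
        with pytest.raises(ValueError):
            og.variable_contribution(runs, panel, "nope")

    def test_planted_signal_ranks_first(self, planted):
        cases, ctrls = planted
        panel = og.VariablePanel(clinical=("signal", "noise0", "noise1", "noise2"))
        runs = og.run_ensemble(cases, ctrls, panel, reps=2, master_seed=20)
        table = og.rank_variables(runs, panel)
        assert table.iloc[0]["variable"] == "signal"
        assert table.iloc[0]["contribution"] > 0

    def test_tie_broken_by_panel_order(self):
        panel = panel_of(2)
        runs = pd.DataFrame({"subset": [1, 2, 3], "rep": 1, "error": 0.5})
        table = og.rank_variables(runs, panel)
        assert list(table["variable"]) == ["v0", "v1"]
        assert list(table["rank"]) == [1, 2]


class TestSklearnWrapper:
    def test_fit_exposes_ranking(self, planted):
        cases, ctrls = planted
        frame = pd.concat([cases, ctrls], ignore_index=True)
        X = frame[["signal", "noise0", "noise1"]]
        y = frame["status"].to_numpy()
        est = og.SubsetEnsembleImportance(reps=2, random_state=21).fit(X, y)
        assert sorted(est.ranking_) == [1, 2, 3]
        assert est.importances_.iloc[0]["variable"] == "signal"
        assert est.contributions_.shape == (3,)

    def test_get_params_roundtrip(self):
        est = og.SubsetEnsembleImportance(reps=5)
        assert og.SubsetEnsembleImportance(**est.get_params()).reps == 5
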