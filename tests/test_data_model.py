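import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satmodels import data_model as dm
from satmodels.data_model import (RowError, SchemaError, TrialTable,
                                  apply_subject_exclusions, preprocess,
                                  read_trials, rt_quantiles, summarize_cell,
                                  vincentize, write_trials)
from satmodels.simulate import StudyConfig, generate_study

from conftest import make_table, make_trials


class TestReadTrials:
    def test_wellformed_table_parses(self, tmp_path):
        df = make_trials(n=4)
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = read_trials(path)
        assert len(table) == 4

    def test_missing_column_is_schema_error(self, tmp_path):
        df = make_trials(n=4).drop(columns="cue")
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="cue"):
            read_trials(path)

    def test_negative_rt_names_offending_row(self, tmp_path):
        df = make_trials(n=5)
        df.loc[3, "rt_ms"] = -5.0
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.raises(RowError) as exc:
            read_trials(path)
        assert 3 in exc.value.rows

    def test_round_trip_preserves_fields(self, tmp_path):
        table = generate_study(StudyConfig(n_subjects=2,
                                           trials_per_cue_per_session=20,
                                           seed=5))
        path = tmp_path / "study.csv"
        write_trials(table, path)
        back = read_trials(path, {"keep_default_na": False,
                                  "na_values": [""]})
        # feedback column survives the trip alongside the required schema
        assert table.equals(TrialTable(back.df))


class TestPreprocess:
    def test_counts_no_response_removals(self):
        responded = np.ones(100, dtype=bool)
        responded[[10, 50]] = False
        t = TrialTable(pd.concat([
            make_trials(n=100, responded=responded, session="placebo"),
            make_trials(n=20, session="placebo", cue="speed"),
        ], ignore_index=True))
        out = preprocess(t)
        assert len(out) == 118
        assert out.metadata["n_no_response_removed"] == 2

    def test_identity_when_clean_and_idempotent(self, small_table):
        once = preprocess(small_table)
        assert len(once) == len(small_table)
        twice = preprocess(once)
        assert once.equals(twice)
        assert twice.metadata["n_no_response_removed"] == 0

    def test_summaries_invariant_to_direction_labels(self, small_table):
        flipped = small_table.copy()
        swap = {"left": "right", "right": "left"}
        flipped.df["direction"] = flipped.df["direction"].map(swap)
        flipped.df["response"] = flipped.df["response"].map(
            lambda r: swap.get(r, r))
        a = summarize_cell(preprocess(small_table), "placebo", "accuracy")
        b = summarize_cell(preprocess(flipped), "placebo", "accuracy")
        assert a.p_correct == b.p_correct
        np.testing.assert_allclose(a.correct_quantiles, b.correct_quantiles)

    def test_cell_emptied_by_removals_raises(self):
        t = TrialTable(pd.concat([
            make_trials(n=10, cue="speed"),
            make_trials(n=5, cue="accuracy",
                        responded=np.zeros(5, dtype=bool)),
        ], ignore_index=True))
        with pytest.raises(dm.PreprocessingError, match="accuracy"):
            preprocess(t)


class TestSubjectExclusions:
    @staticmethod
    def _cohort(acc_counts):
        """One subject per entry, with `count` correct of 100 accuracy trials."""
        frames = []
        for i, n_correct in enumerate(acc_counts):
            correct = np.zeros(100, dtype=bool)
            correct[:n_correct] = True
            for session in ("drug", "placebo"):
                frames.append(make_trials(f"s{i:02d}", session, "accuracy",
                                          n=100, correct=correct, seed=i))
                frames.append(make_trials(f"s{i:02d}", session, "speed",
                                          n=20, seed=100 + i))
        return preprocess(TrialTable(pd.concat(frames, ignore_index=True)))

    def test_strict_threshold_boundary(self):
        t = self._cohort([59, 60, 90])
        out = apply_subject_exclusions(t, min_accuracy=0.60)
        assert out.metadata["excluded_subjects"] == ["s00"]
        assert set(out.subjects) == {"s01", "s02"}

    def test_all_excluded_raises(self):
        t = self._cohort([40, 30])
        with pytest.raises(ValueError, match="every subject"):
            apply_subject_exclusions(t, min_accuracy=0.60)

    def test_planted_low_drift_subjects_are_caught(self):
        """Subjects generated with near-chance drift fail the 60% rule."""
        good = generate_study(StudyConfig(n_subjects=5,
                                          trials_per_cue_per_session=40,
                                          seed=21))
        weak_cfg = StudyConfig(n_subjects=2, trials_per_cue_per_session=40,
                               seed=22)
        weak_cfg.ddm_population.update({"v_mean": 0.005, "v_sd": 0.0})
        weak = generate_study(weak_cfg)
        weak.df["subject"] = weak.df["subject"].map(
            lambda s: f"w{s[1:]}")
        merged = preprocess(TrialTable(
            pd.concat([good.df, weak.df], ignore_index=True)))
        out = apply_subject_exclusions(merged, min_accuracy=0.60)
        assert out.metadata["excluded_subjects"] == ["w00", "w01"]


class TestQuantiles:
    def test_constant_sample(self):
        np.testing.assert_allclose(rt_quantiles([0.4] * 7), [0.4] * 5)

    def test_matches_order_statistic_interpolation_oracle(self):
        x = np.arange(1.0, 101.0)
        # independent oracle: explicit type-7 interpolation over sorted values
        def oracle(sample, p):
            s = np.sort(sample)
            h = (len(s) - 1) * p
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, len(s) - 1)] - s[lo])
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            got = rt_quantiles(x, [p])[0]
            assert got == pytest.approx(oracle(x, p), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.2, 1.0, 57)
        np.testing.assert_allclose(rt_quantiles(x),
                                   rt_quantiles(rng.permutation(x)))

    def test_errors(self):
        with pytest.raises(ValueError):
            rt_quantiles([])
        with pytest.raises(ValueError):
            rt_quantiles([1.0, 2.0], [0.0, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.1, 2.0), min_size=1, max_size=40))
    def test_nondecreasing_for_any_sample(self, xs):
        q = rt_quantiles(xs)
        assert np.all(np.diff(q) >= -1e-12)


class TestSummarizeCell:
    def test_p_correct(self):
        correct = np.concatenate([np.ones(80, bool), np.zeros(20, bool)])
        t = preprocess(TrialTable(make_trials(n=100, correct=correct)))
        s = summarize_cell(t, "placebo", "accuracy")
        assert s.p_correct == pytest.approx(0.8)
        assert s.error_quantiles is not None

    def test_sparse_errors_flagged(self):
        correct = np.ones(50, bool)
        correct[:3] = False
        t = preprocess(TrialTable(make_trials(n=50, correct=correct)))
        s = summarize_cell(t, "placebo", "accuracy")
        assert s.sparse_errors and s.error_quantiles is None

    def test_empty_cell_raises(self, small_table):
        with pytest.raises(ValueError, match="no responded"):
            summarize_cell(preprocess(small_table), "placebo", "accuracy",
                           subject="missing")


class TestVincentize:
    @staticmethod
    def _summary(med, n=51, session="placebo", cue="speed", seed=0):
        rng = np.random.default_rng(seed)
        rt = np.sort(rng.uniform(0.2, 1.0, n))
        rt = rt - np.median(rt) + med
        t = preprocess(TrialTable(make_trials(
            n=n, rt_ms=rt * 1000, session=session, cue=cue,
            correct=np.ones(n, bool))))
        return summarize_cell(t, session, cue)

    def test_identical_subjects_average_to_themselves(self):
        s = self._summary(0.5)
        g = vincentize([s, s, s])
        np.testing.assert_allclose(g.correct_quantiles, s.correct_quantiles)
        assert g.p_correct == pytest.approx(s.p_correct)

    def test_group_median_is_mean_of_subject_medians(self):
        a, b = self._summary(0.4, seed=1), self._summary(0.6, seed=2)
        g = vincentize([a, b])
        assert g.correct_quantiles[2] == pytest.approx(0.5, abs=1e-12)

    def test_mismatched_grids_raise(self):
        a = self._summary(0.4)
        b = summarize_cell(
            preprocess(TrialTable(make_trials(n=30, cue="speed"))),
            "placebo", "speed", probs=(0.25, 0.5, 0.75))
        with pytest.raises(ValueError, match="grids"):
            vincentize([a, b])

    def test_within_subject_envelope(self):
        subs = [self._summary(m, seed=i) for i, m in
                enumerate((0.35, 0.5, 0.62, 0.44))]
        g = vincentize(subs)
        stack = np.stack([s.correct_quantiles for s in subs])
        assert np.all(g.correct_quantiles >= stack.min(axis=0) - 1e-12)
        assert np.all(g.correct_quantiles <= stack.max(axis=0) + 1e-12)

    def test_commutes_with_constant_shift(self):
        subs = [self._summary(m, seed=i) for i, m in enumerate((0.4, 0.55))]
        shifted = [self._summary(m + 0.1, seed=i)
                   for i, m in enumerate((0.4, 0.55))]
        g0, g1 = vincentize(subs), vincentize(shifted)
        np.testing.assert_allclose(g1.correct_quantiles,
                                   g0.correct_quantiles + 0.1, atol=1e-9)
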