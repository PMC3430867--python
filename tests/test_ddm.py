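import numpy as np
import pandas as pd
import pytest

from satmodels import data_model as dm
from satmodels import ddm
from satmodels.data_model import TrialTable
from satmodels.ddm import (DDMCoreParams, DDMSessionParams, FitConfig,
                           chi_square_statistic, choice_probability,
                           ddm_bin_probabilities, ddm_chi_square,
                           ddm_defective_cdf, fit_ddm, wiener_fpt_density)
from satmodels.simulate import simulate_ddm_trials


def closed_form_p_upper(p: DDMCoreParams) -> float:
    """Absorption probability at the upper barrier of drifted Brownian
    motion between two absorbing barriers (independent oracle)."""
    if p.v == 0:
        return p.z / p.a
    k = 2.0 * p.v / p.s ** 2
    return (1.0 - np.exp(-k * p.z)) / (1.0 - np.exp(-k * p.a))


PARAMS = DDMCoreParams(a=0.16, z=0.08, v=0.25, ter=0.0, s=0.1)


class TestDensity:
    def test_no_mass_before_zero(self):
        assert wiener_fpt_density(np.array([-0.1, 0.0]), "correct", PARAMS).max() == 0

    def test_symmetry_at_zero_drift(self):
        p = DDMCoreParams(a=0.16, z=0.08, v=0.0, ter=0.0, s=0.1)
        t = np.linspace(0.01, 2.0, 50)
        np.testing.assert_allclose(wiener_fpt_density(t, "correct", p),
                                   wiener_fpt_density(t, "error", p))

    @pytest.mark.parametrize("eta", [0.0, 0.08])
    def test_total_mass_is_one(self, eta):
        p = DDMCoreParams(a=0.16, z=0.08, v=0.25, ter=0.0, eta=eta, s=0.1)
        t = np.linspace(0.0, 12.0, 30000)
        mass = np.trapezoid(wiener_fpt_density(t, "correct", p)
                            + wiener_fpt_density(t, "error", p), t)
        assert mass == pytest.approx(1.0, abs=1e-4)

    def test_series_branches_agree_in_overlap(self):
        """Small- and large-time series agree where both are converged."""
        a1, w = 1.6, 0.5
        u = np.linspace(0.05, 0.6, 30)  # scaled time overlap region
        small = ddm._ftt_small(u, w, 25)
        large = ddm._ftt_large(u, w, 200)
        np.testing.assert_allclose(small, large, atol=1e-6)

    def test_matches_simulated_histogram(self):
        """Bridge-corrected path simulation reproduces the series density."""
        frag = simulate_ddm_trials(PARAMS, 40000, deadline=10.0, seed=9,
                                   dt=1e-3)
        resp = frag[frag.responded]
        rt = resp.rt_ms.to_numpy() / 1000.0
        corr = resp.correct.to_numpy(bool)
        edges = np.linspace(0.0, 1.2, 13)
        grid = np.linspace(0, 1.2, 2000)
        f = wiener_fpt_density(grid, "correct", PARAMS)
        model = np.array([
            np.trapezoid(f[(grid >= lo) & (grid <= hi)],
                         grid[(grid >= lo) & (grid <= hi)])
            for lo, hi in zip(edges[:-1], edges[1:])])
        obs = np.histogram(rt[corr], bins=edges)[0] / len(frag)
        assert np.max(np.abs(obs - model)) < 4.0 / np.sqrt(len(frag))


class TestDefectiveCDF:
    def test_zero_at_origin_and_monotone(self):
        t = np.linspace(0.0, 3.0, 40)
        F = ddm_defective_cdf(t, "correct", PARAMS)
        assert F[0] == 0.0
        assert np.all(np.diff(F) >= -1e-12)

    def test_symmetric_limits_are_half(self):
        p = DDMCoreParams(a=0.16, z=0.08, v=0.0, ter=0.0, s=0.1)
        assert choice_probability("correct", p) == pytest.approx(0.5, abs=1e-4)
        assert choice_probability("error", p) == pytest.approx(0.5, abs=1e-4)

    @pytest.mark.parametrize("a,z,v", [(0.16, 0.08, 0.25), (0.08, 0.04, 0.25),
                                       (0.16, 0.06, 0.10), (0.12, 0.08, 0.30)])
    def test_limit_matches_closed_form_absorption(self, a, z, v):
        p = DDMCoreParams(a=a, z=z, v=v, ter=0.0, s=0.1)
        assert choice_probability("correct", p) == pytest.approx(
            closed_form_p_upper(p), abs=1e-4)
        assert (choice_probability("correct", p)
                + choice_probability("error", p)) == pytest.approx(1.0, abs=2e-4)


class TestBinProbabilities:
    SP = DDMSessionParams(a_speed=0.08, a_accuracy=0.16, ter_speed=0.30,
                          ter_accuracy=0.35, v=0.25)

    def test_bins_sum_to_one(self):
        edges = np.array([0.45, 0.55, 0.65, 0.8, 1.0])
        c, e = ddm_bin_probabilities(self.SP, "accuracy", edges, edges)
        assert len(c) == 6 and len(e) == 6
        assert np.all(c >= 0) and np.all(e >= 0)
        assert c.sum() + e.sum() == pytest.approx(1.0, abs=1e-3)

    def test_huge_edges_telescope_to_choice_probabilities(self):
        c, e = ddm_bin_probabilities(self.SP, "accuracy",
                                     np.array([50.0]), np.array([50.0]))
        core = self.SP.core("accuracy")
        assert c[0] == pytest.approx(closed_form_p_upper(core), abs=1e-3)
        assert e[0] == pytest.approx(1 - closed_form_p_upper(core), abs=1e-3)

    def test_zero_drift_mirrored_edges_are_mirrored(self):
        p = DDMSessionParams(a_speed=0.08, a_accuracy=0.16, ter_speed=0.3,
                             ter_accuracy=0.3, v=0.0)
        edges = np.array([0.4, 0.5, 0.7])
        c, e = ddm_bin_probabilities(p, "accuracy", edges, edges)
        np.testing.assert_allclose(c, e, atol=1e-10)

    def test_collapsed_error_bin(self):
        edges = np.array([0.45, 0.55, 0.65, 0.8, 1.0])
        c, e = ddm_bin_probabilities(self.SP, "accuracy", edges, None)
        assert len(e) == 1
        core = self.SP.core("accuracy")
        assert e[0] == pytest.approx(1 - closed_form_p_upper(core), abs=1e-3)

    def test_bins_match_simulated_proportions(self):
        core = self.SP.core("accuracy")
        frag = simulate_ddm_trials(core, 40000, deadline=10.0, seed=4, dt=1e-3)
        resp = frag[frag.responded]
        rt = resp.rt_ms.to_numpy() / 1000.0
        corr = resp.correct.to_numpy(bool)
        edges = np.quantile(rt[corr], [0.1, 0.3, 0.5, 0.7, 0.9])
        e_edges = np.quantile(rt[~corr], [0.1, 0.3, 0.5, 0.7, 0.9])
        c, e = ddm_bin_probabilities(self.SP, "accuracy", edges, e_edges)
        obs_c = np.histogram(rt[corr], bins=np.r_[0, edges, 99])[0] / len(frag)
        obs_e = np.histogram(rt[~corr], bins=np.r_[0, e_edges, 99])[0] / len(frag)
        tol = 4.0 / np.sqrt(len(frag))
        assert np.max(np.abs(c - obs_c)) < tol
        assert np.max(np.abs(e - obs_e)) < tol


class TestChiSquare:
    def test_hand_summation_oracle(self):
        obs = np.array([0.10, 0.20, 0.20, 0.20, 0.20, 0.10])
        exp = np.full(6, 1 / 6)
        assert chi_square_statistic(100, obs, exp) == pytest.approx(8.0, abs=1e-9)

    def test_zero_iff_observed_equals_expected(self):
        exp = np.full(6, 1 / 6)
        assert chi_square_statistic(500, exp, exp) == 0.0

    def test_linear_in_n(self):
        obs = np.array([0.1, 0.25, 0.25, 0.2, 0.15, 0.05])
        exp = np.full(6, 1 / 6)
        assert chi_square_statistic(200, obs, exp) == pytest.approx(
            2 * chi_square_statistic(100, obs, exp))

    def test_session_chi_square_matches_explicit_summation(self):
        rng = np.random.default_rng(0)
        frames = []
        p = TestBinProbabilities.SP
        for cue in ("speed", "accuracy"):
            core = p.core(cue)
            frames.append(simulate_ddm_trials(core, 600, 10.0, rng, dt=1e-3,
                                              cue=cue))
        table = dm.preprocess(TrialTable(pd.concat(frames, ignore_index=True)))
        summaries = dm.summarize_subject_session(table, "s0", "placebo")
        got = ddm_chi_square(summaries, p)
        # independent re-summation from the bin-probability primitives
        expected = 0.0
        for cue in ("speed", "accuracy"):
            s = summaries[cue]
            exp_c, exp_e = ddm_bin_probabilities(
                p, cue, s.correct_quantiles, s.error_quantiles, n_grid=1536)
            obs_c = s.p_correct * np.array([.1, .2, .2, .2, .2, .1])
            if s.error_quantiles is None:
                obs_e = np.array([1 - s.p_correct])
            else:
                obs_e = (1 - s.p_correct) * np.array([.1, .2, .2, .2, .2, .1])
            for o, x in zip(np.r_[obs_c, obs_e], np.r_[exp_c, exp_e]):
                x = max(x, 1e-5)
                expected += s.n_trials * (o - x) ** 2 / x
        assert got == pytest.approx(expected, rel=1e-10)


class TestThresholdEffects:
    def test_raising_threshold_raises_accuracy_and_slows_decisions(self):
        grid = [0.08, 0.12, 0.16, 0.24]
        accs, means = [], []
        for a in grid:
            p = DDMCoreParams(a=a, z=a / 2, v=0.25, ter=0.0, s=0.1)
            t = np.linspace(0, 30, 30000)
            fc = wiener_fpt_density(t, "correct", p)
            fe = wiener_fpt_density(t, "error", p)
            pc = np.trapezoid(fc, t)
            accs.append(pc)
            means.append(np.trapezoid(t * (fc + fe), t))
        assert np.all(np.diff(accs) > 0)
        assert np.all(np.diff(means) > 0)


class TestFit:
    @staticmethod
    def _summaries(seed=0, n=2000):
        rng = np.random.default_rng(seed)
        truth = TestBinProbabilities.SP
        frames = []
        for cue in ("speed", "accuracy"):
            frames.append(simulate_ddm_trials(truth.core(cue), n, 10.0, rng,
                                              dt=2e-4, cue=cue))
        table = dm.preprocess(TrialTable(pd.concat(frames, ignore_index=True)))
        return dm.summarize_subject_session(table, "s0", "placebo")

    def test_recovers_planted_thresholds(self):
        summaries = self._summaries(seed=12)
        fit = fit_ddm(summaries, FitConfig(n_restarts=2, seed=5))
        truth = TestBinProbabilities.SP
        assert fit.params.a_speed < fit.params.a_accuracy
        assert fit.params.a_speed == pytest.approx(truth.a_speed, rel=0.10)
        assert fit.params.a_accuracy == pytest.approx(truth.a_accuracy, rel=0.10)
        assert fit.params.ter_speed == pytest.approx(truth.ter_speed, rel=0.10)
        assert fit.params.ter_accuracy == pytest.approx(truth.ter_accuracy,
                                                        rel=0.10)

    def test_optimum_is_local_minimum_and_consistent(self):
        summaries = self._summaries(seed=3, n=400)
        cfg = FitConfig(n_restarts=2, seed=1, maxiter=600)
        fit = fit_ddm(summaries, cfg)
        # reported objective equals a fresh evaluation at the optimum
        assert ddm_chi_square(summaries, fit.params,
                              n_grid=cfg.n_grid) == pytest.approx(fit.chi2)
        # and beats arbitrary interior start points
        for a_sp, a_ac in ((0.10, 0.20), (0.06, 0.30)):
            other = DDMSessionParams(a_sp, a_ac, 0.25, 0.25, 0.3)
            assert fit.chi2 <= ddm_chi_square(summaries, other,
                                              n_grid=cfg.n_grid) + 1e-9

    def test_same_seed_same_fit(self):
        summaries = self._summaries(seed=7, n=300)
        cfg = dict(n_restarts=2, seed=42, maxiter=400)
        f1 = fit_ddm(summaries, FitConfig(**cfg))
        f2 = fit_ddm(summaries, FitConfig(**cfg))
        assert f1.params == f2.params
        assert f1.chi2 == f2.chi2


class TestValidation:
    def test_invalid_params_raise(self):
        with pytest.raises(ddm.ParameterError):
            DDMCoreParams(a=0.16, z=0.20, v=0.2, ter=0.3)
        with pytest.raises(ddm.ParameterError):
            DDMCoreParams(a=-0.1, z=-0.05, v=0.2, ter=0.3)
        with pytest.raises(ValueError, match="boundary"):
            wiener_fpt_density(0.5, "upper", PARAMS)
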