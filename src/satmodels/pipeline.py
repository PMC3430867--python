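"""End-to-end behavioral analysis pipeline and parameter-recovery harness.

`run_behavioral_analysis` reproduces the study's analysis sequence on any
validated trial table: preprocessing -> subject exclusions -> summary
statistics -> RT/accuracy 2x2 within-subject ANOVAs -> per-subject DDM fits
(one per session) -> one joint LBA fit per subject -> threshold ANOVAs ->
paired and default Bayesian t-tests on drug-minus-placebo difference scores
-> trait-covariate correlation screen -> vincentized quantile summaries
with model predictions.  Every stage is logged and the report is
deterministic given the data, configuration and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import data_model as dm
from . import ddm, lba, stats
from .data_model import CUES, SESSIONS, TrialTable
from .simulate import StudyConfig, generate_study, simulate_ddm_trials, \
    simulate_lba_trials, study_traits


@dataclass
class AnalysisConfig:
    seed: int = 0
    min_accuracy: float = 0.60
    apply_exclusions: bool = True
    fit_ddm_models: bool = True
    fit_lba_models: bool = True
    run_correlations: bool = True
    prior_h0: float = 0.5
    r_scale: float = stats.DEFAULT_R_SCALE
    family_alpha: float = 0.05
    ddm_fit: ddm.FitConfig = field(default_factory=lambda: ddm.FitConfig(n_restarts=3))
    lba_fit: lba.LBAFitConfig = field(default_factory=lambda: lba.LBAFitConfig(n_restarts=3))

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        ddm_cfg = ddm.FitConfig.from_dict(d.pop("ddm_fit", {}))
        lba_cfg = lba.LBAFitConfig.from_dict(d.pop("lba_fit", {}))
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(ddm_fit=ddm_cfg, lba_fit=lba_cfg, **known)


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if not np.isfinite(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class AnalysisReport:
    """Structured pipeline output; `to_json` is byte-stable given the inputs."""

    provenance: dict
    stages: list
    exclusions: dict
    cell_stats: list
    anovas: dict
    ddm_fits: dict
    lba_fits: dict
    threshold_anovas: dict
    comparisons: list
    correlations: list | None
    vincentized: dict

    def body(self) -> dict:
        return {
            "provenance": self.provenance,
            "stages": self.stages,
            "exclusions": self.exclusions,
            "cell_stats": self.cell_stats,
            "anovas": self.anovas,
            "ddm_fits": self.ddm_fits,
            "lba_fits": self.lba_fits,
            "threshold_anovas": self.threshold_anovas,
            "comparisons": self.comparisons,
            "correlations": self.correlations,
            "vincentized": self.vincentized,
        }

    def to_json(self) -> str:
        return json.dumps(_round_floats(self.body()), indent=1, sort_keys=True)

    def summary_text(self) -> str:
        lines = ["Behavioral analysis summary", "=" * 27]
        lines.append(f"subjects analysed: {self.provenance['n_subjects_analysed']} "
                     f"(excluded: {self.exclusions['excluded_subjects']})")
        for name, res in self.anovas.items():
            eff = ", ".join(f"{k}: F(1,{res['df'][1]})={res['F'][k]:.3g} "
                            f"p={res['p'][k]:.3g}" for k in res["F"])
            lines.append(f"{name} ANOVA: {eff}")
        for comp in self.comparisons:
            if "posterior_h0" not in comp:
                continue
            lines.append(
                f"{comp['measure']} [{comp['condition']}] drug-placebo: "
                f"t({comp['df']})={comp['t']:.3g} p={comp['p']:.3g} "
                f"pBayes(H0)={comp['posterior_h0']:.3f}")
        return "\n".join(lines)


def _table_hash(table: TrialTable) -> str:
    csv = table.df.to_csv(index=False)
    return hashlib.sha256(csv.encode()).hexdigest()[:16]


def _summary_to_dict(s: dm.QuantileSummary) -> dict:
    return {
        "session": s.session, "cue": s.cue, "n_trials": s.n_trials,
        "n_correct": s.n_correct, "n_error": s.n_error,
        "p_correct": s.p_correct, "probs": list(s.probs),
        "correct_quantiles": s.correct_quantiles,
        "error_quantiles": None if s.error_quantiles is None else s.error_quantiles,
        "sparse_errors": s.sparse_errors,
    }


def _anova_to_dict(res: stats.AnovaResult) -> dict:
    return {"F": res.F, "p": res.p, "df": list(res.df),
            "cell_means": res.cell_means, "ss": res.ss}


def _comparison(measure: str, condition: str, drug_vals, placebo_vals,
                cfg: AnalysisConfig) -> dict:
    tt = stats.paired_t_test(drug_vals, placebo_vals)
    bt = stats.bayes_t_test_from_t(tt.t, len(drug_vals), cfg.r_scale, cfg.prior_h0)
    return {"measure": measure, "condition": condition,
            "t": tt.t, "df": tt.df, "p": tt.p, "mean_diff": tt.mean_diff,
            "bf01": bt.bf01, "posterior_h0": bt.posterior_h0,
            "prior_h0": bt.prior_h0, "r_scale": bt.r_scale, "n": bt.n}


def run_behavioral_analysis(table: TrialTable,
                            cfg: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full behavioral pipeline on a validated trial table."""
    cfg = cfg or AnalysisConfig()
    stages: list[dict] = []

    def stage(name, **info):
        stages.append({"stage": name, **_round_floats(info)})

    input_hash = _table_hash(table)
    pre = dm.preprocess(table)
    stage("preprocess", n_dummy=pre.metadata.get("n_dummy_removed", 0),
          n_no_response=pre.metadata.get("n_no_response_removed", 0))

    if cfg.apply_exclusions:
        analysed = dm.apply_subject_exclusions(pre, cfg.min_accuracy)
    else:
        analysed = pre
        analysed.metadata["excluded_subjects"] = []
    exclusions = {"excluded_subjects": analysed.metadata["excluded_subjects"],
                  "min_accuracy": cfg.min_accuracy,
                  "applied": cfg.apply_exclusions}
    stage("exclusions", **exclusions)

    subjects = analysed.subjects
    df = analysed.df

    # per-cell summary statistics, subject-level matrices for the ANOVAs
    cell_stats = []
    rt_cells = np.zeros((len(subjects), 4))
    acc_cells = np.zeros((len(subjects), 4))
    order = [(s, c) for s in SESSIONS for c in CUES]  # drug varies slowest
    for j, (session, cue) in enumerate(order):
        sub = df[(df["session"] == session) & (df["cue"] == cue)]
        cell_stats.append({
            "session": session, "cue": cue, "n_trials": int(len(sub)),
            "mean_rt_s": float(sub["rt_ms"].mean() / 1000.0),
            "accuracy": float(sub["correct"].mean()),
        })
        for i, subject in enumerate(subjects):
            srows = sub[sub["subject"] == subject]
            rt_cells[i, j] = srows["rt_ms"].mean() / 1000.0
            acc_cells[i, j] = srows["correct"].mean()
    stage("summary_stats", n_cells=len(cell_stats))

    anovas = {
        "rt": _anova_to_dict(stats.rm_anova_2x2(rt_cells, ("drug", "cue"))),
        "accuracy": _anova_to_dict(stats.rm_anova_2x2(acc_cells, ("drug", "cue"))),
    }
    stage("anovas")

    # per-subject quantile summaries (also reused for vincentizing)
    summaries: dict = {}
    for subject in subjects:
        summaries[subject] = {
            session: dm.summarize_subject_session(analysed, subject, session)
            for session in SESSIONS}

    # model fits
    ddm_fits: dict = {}
    lba_fits: dict = {}
    rng = np.random.default_rng(cfg.seed)
    if cfg.fit_ddm_models:
        for subject in subjects:
            ddm_fits[subject] = {}
            for session in SESSIONS:
                fit_cfg = ddm.FitConfig(**{**cfg.ddm_fit.__dict__,
                                           "seed": int(rng.integers(2 ** 31))})
                fit = ddm.fit_ddm(summaries[subject][session], fit_cfg)
                ddm_fits[subject][session] = json.loads(fit.to_json())
        stage("ddm_fits", n_fits=2 * len(subjects))
    if cfg.fit_lba_models:
        for subject in subjects:
            sub_table = TrialTable(df[df["subject"] == subject].reset_index(drop=True))
            fit_cfg = lba.LBAFitConfig(**{**cfg.lba_fit.__dict__,
                                          "seed": int(rng.integers(2 ** 31))})
            fit = lba.fit_lba(sub_table, fit_cfg)
            lba_fits[subject] = json.loads(fit.to_json())
        stage("lba_fits", n_fits=len(subjects))

    # threshold ANOVAs (session x condition, both models)
    threshold_anovas: dict = {}
    ddm_thr = None
    lba_thr = None
    if ddm_fits:
        ddm_thr = np.array([
            [ddm_fits[s]["drug"]["params"]["a_speed"],
             ddm_fits[s]["drug"]["params"]["a_accuracy"],
             ddm_fits[s]["placebo"]["params"]["a_speed"],
             ddm_fits[s]["placebo"]["params"]["a_accuracy"]]
            for s in subjects])
        threshold_anovas["ddm"] = _anova_to_dict(
            stats.rm_anova_2x2(ddm_thr, ("drug", "cue")))
    if lba_fits:
        lba_thr = np.array([
            [lba_fits[s]["params"]["b"]["drug/speed"],
             lba_fits[s]["params"]["b"]["drug/accuracy"],
             lba_fits[s]["params"]["b"]["placebo/speed"],
             lba_fits[s]["params"]["b"]["placebo/accuracy"]]
            for s in subjects])
        threshold_anovas["lba"] = _anova_to_dict(
            stats.rm_anova_2x2(lba_thr, ("drug", "cue")))
    if threshold_anovas:
        stage("threshold_anovas", models=sorted(threshold_anovas))

    # paired + Bayesian t-tests on drug-minus-placebo difference scores
    comparisons = []
    for j, cue in enumerate(CUES):
        comparisons.append(_comparison(
            "rt", cue, rt_cells[:, j], rt_cells[:, 2 + j], cfg))
        comparisons.append(_comparison(
            "accuracy", cue, acc_cells[:, j], acc_cells[:, 2 + j], cfg))
    if ddm_thr is not None:
        for j, cue in enumerate(CUES):
            comparisons.append(_comparison(
                "ddm_threshold", cue, ddm_thr[:, j], ddm_thr[:, 2 + j], cfg))
        # within-session cue contrasts (speed vs accuracy thresholds)
        for session, (j0, j1) in (("drug", (0, 1)), ("placebo", (2, 3))):
            tt = stats.paired_t_test(ddm_thr[:, j0], ddm_thr[:, j1])
            comparisons.append({"measure": "ddm_threshold_cue_contrast",
                                "condition": session, "t": tt.t, "df": tt.df,
                                "p": tt.p, "mean_diff": tt.mean_diff})
    if lba_thr is not None:
        for j, cue in enumerate(CUES):
            comparisons.append(_comparison(
                "lba_threshold", cue, lba_thr[:, j], lba_thr[:, 2 + j], cfg))
        for session, (j0, j1) in (("drug", (0, 1)), ("placebo", (2, 3))):
            tt = stats.paired_t_test(lba_thr[:, j0], lba_thr[:, j1])
            comparisons.append({"measure": "lba_threshold_cue_contrast",
                                "condition": session, "t": tt.t, "df": tt.df,
                                "p": tt.p, "mean_diff": tt.mean_diff})
    stage("comparisons", n=len(comparisons))

    # correlation screen against trait covariates, if present
    correlations = None
    if (cfg.run_correlations and table.metadata.get("traits")
            and len(subjects) >= 3):
        traits = study_traits(table).loc[subjects]
        effects = pd.DataFrame({
            f"{m}_{cue}_effect": vals[:, j] - vals[:, 2 + j]
            for m, vals in (("rt", rt_cells), ("accuracy", acc_cells))
            for j, cue in enumerate(CUES)
        }, index=subjects)
        correlations = stats.correlation_screen(
            effects, traits, cfg.family_alpha).to_dict("records")
        stage("correlation_screen", n_comparisons=len(correlations))
    else:
        stage("correlation_screen", skipped=True)

    # vincentized group summaries with model predictions
    vincentized: dict = {}
    for session in SESSIONS:
        for cue in CUES:
            key = f"{session}/{cue}"
            group = dm.vincentize([summaries[s][session][cue] for s in subjects])
            entry = {"observed": _summary_to_dict(group)}
            if ddm_fits:
                preds = []
                for s in subjects:
                    p = ddm.DDMSessionParams(**{
                        k: v for k, v in ddm_fits[s][session]["params"].items()})
                    preds.append(ddm.predicted_quantiles(p, cue, group.probs))
                entry["ddm_predicted"] = {
                    "p_correct": float(np.mean([q["p_correct"] for q in preds])),
                    "correct": np.mean([q["correct"] for q in preds], axis=0),
                    "error": np.mean([q["error"] for q in preds], axis=0),
                }
            vincentized[key] = entry
    stage("vincentize")

    provenance = {
        "input_hash": input_hash,
        "seed": cfg.seed,
        "n_subjects_input": len(table.subjects),
        "n_subjects_analysed": len(subjects),
        "config": _round_floats({
            "min_accuracy": cfg.min_accuracy,
            "apply_exclusions": cfg.apply_exclusions,
            "prior_h0": cfg.prior_h0, "r_scale": cfg.r_scale,
            "family_alpha": cfg.family_alpha,
            "ddm_fit": cfg.ddm_fit.__dict__, "lba_fit": cfg.lba_fit.__dict__,
        }),
        "generator_metadata": _round_floats(table.metadata.get("config")),
    }
    return AnalysisReport(
        provenance=provenance, stages=stages, exclusions=exclusions,
        cell_stats=cell_stats, anovas=anovas, ddm_fits=ddm_fits,
        lba_fits=lba_fits, threshold_anovas=threshold_anovas,
        comparisons=comparisons, correlations=correlations,
        vincentized=_round_floats(vincentized))


# ---------------------------------------------------------------------------
# parameter-recovery harness

@dataclass
class RecoveryConfig:
    model: str = "ddm"            # {"ddm", "lba"}
    n_replicates: int = 20
    trials_per_cell: int = 2000
    seed: int = 0
    deadline: float = 10.0        # effectively uncensored for recovery
    ddm_truth: dict = field(default_factory=lambda: {
        "a_speed": 0.08, "a_accuracy": 0.16, "ter_speed": 0.30,
        "ter_accuracy": 0.35, "v": 0.25, "eta": 0.0, "s": 0.1})
    lba_truth: dict = field(default_factory=lambda: {
        "b_speed": 1.0, "b_accuracy": 1.6, "A": 0.8, "v_correct": 3.0,
        "v_error": 1.5, "t0": 0.25, "s_drift": 1.0})
    ddm_fit: ddm.FitConfig = field(default_factory=lambda: ddm.FitConfig(n_restarts=3))
    lba_fit: lba.LBAFitConfig = field(default_factory=lambda: lba.LBAFitConfig(n_restarts=3))
    ddm_dt: float = 2e-4


def _recover_ddm_once(cfg: RecoveryConfig, seed_seq) -> dict:
    t = cfg.ddm_truth
    rng = np.random.default_rng(seed_seq)
    frames = []
    for cue in CUES:
        a = t["a_speed"] if cue == "speed" else t["a_accuracy"]
        ter = t["ter_speed"] if cue == "speed" else t["ter_accuracy"]
        core = ddm.DDMCoreParams(a=a, z=a / 2, v=t["v"], ter=ter,
                                 eta=t["eta"], s=t["s"])
        frames.append(simulate_ddm_trials(core, cfg.trials_per_cell,
                                          cfg.deadline, rng, dt=cfg.ddm_dt,
                                          cue=cue))
    table = dm.preprocess(TrialTable(pd.concat(frames, ignore_index=True)))
    summaries = dm.summarize_subject_session(table, "s0", "placebo")
    fit_cfg = ddm.FitConfig(**{**cfg.ddm_fit.__dict__,
                               "seed": int(rng.integers(2 ** 31))})
    fit = ddm.fit_ddm(summaries, fit_cfg)
    est = fit.params
    return {"truth": {k: t[k] for k in ("a_speed", "a_accuracy", "ter_speed",
                                        "ter_accuracy", "v")},
            "estimate": {"a_speed": est.a_speed, "a_accuracy": est.a_accuracy,
                         "ter_speed": est.ter_speed, "ter_accuracy": est.ter_accuracy,
                         "v": est.v},
            "chi2": fit.chi2}


def _recover_lba_once(cfg: RecoveryConfig, seed_seq,
                      drug_mult: float = 1.0) -> dict:
    t = cfg.lba_truth
    rng = np.random.default_rng(seed_seq)
    frames = []
    truth_b = {}
    for session in SESSIONS:
        mult = drug_mult if session == "drug" else 1.0
        for cue in CUES:
            b = (t["b_speed"] if cue == "speed" else t["b_accuracy"]) * mult
            truth_b[f"{session}/{cue}"] = b
            p = lba.LBAParams(b={(session, cue): b}, A=t["A"],
                              v_correct=t["v_correct"], v_error=t["v_error"],
                              t0=t["t0"], s_drift=t["s_drift"])
            frames.append(simulate_lba_trials(p, (session, cue),
                                              cfg.trials_per_cell,
                                              cfg.deadline, rng))
    table = dm.preprocess(TrialTable(pd.concat(frames, ignore_index=True)))
    fit_cfg = lba.LBAFitConfig(**{**cfg.lba_fit.__dict__,
                                  "seed": int(rng.integers(2 ** 31))})
    fit = lba.fit_lba(table, fit_cfg)
    return {"truth": {"b": truth_b, "A": t["A"], "v_correct": t["v_correct"],
                      "v_error": t["v_error"], "t0": t["t0"]},
            "estimate": json.loads(fit.to_json())["params"],
            "loglik": fit.loglik}


def run_parameter_recovery(cfg: RecoveryConfig | None = None) -> pd.DataFrame:
    """Truth-vs-estimate table over seeded replicate simulate-and-fit runs."""
    cfg = cfg or RecoveryConfig()
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(max(cfg.n_replicates, 0))
    rows = []
    for r in range(cfg.n_replicates):
        if cfg.model == "ddm":
            rec = _recover_ddm_once(cfg, seeds[r])
            for k, truth in rec["truth"].items():
                est = rec["estimate"][k]
                rows.append({"replicate": r, "parameter": k, "truth": truth,
                             "estimate": est, "bias": est - truth,
                             "rel_error": abs(est - truth) / abs(truth)})
        elif cfg.model == "lba":
            rec = _recover_lba_once(cfg, seeds[r])
            flat_truth = dict(rec["truth"]["b"])
            for k in ("A", "v_correct", "v_error", "t0"):
                flat_truth[k] = rec["truth"][k]
            flat_est = dict(rec["estimate"]["b"])
            for k in ("A", "v_correct", "v_error", "t0"):
                flat_est[k] = rec["estimate"][k]
            for k, truth in flat_truth.items():
                est = flat_est[k]
                rows.append({"replicate": r, "parameter": k, "truth": truth,
                             "estimate": est, "bias": est - truth,
                             "rel_error": abs(est - truth) / abs(truth)})
        else:
            raise ValueError(f"unknown model {cfg.model!r}")
    return pd.DataFrame(rows, columns=["replicate", "parameter", "truth",
                                       "estimate", "bias", "rel_error"])
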