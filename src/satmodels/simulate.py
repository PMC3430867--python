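"""Seeded generators for DDM/LBA trials and full synthetic two-session studies.

The study generator emulates a cued two-choice random-dot-motion task: each
subject completes a drug and a placebo session, each session two blocks of
50 speed-cue, 50 accuracy-cue and 5 dummy (fixation-only) trials, with a
response window after which a trial is recorded as a non-response.  Subject
parameters are drawn from population distributions; the speed cue lowers
the decision threshold by a multiplicative factor, and a configurable drug
effect (none, by default) scales thresholds in the drug session.  Trait
covariates (behavioural inhibition/activation and impulsiveness scores) are
attached per subject with a configurable correlation to the subject's drug
effect.

DDM trials are simulated by Euler-Maruyama steps with a Brownian-bridge
crossing correction (the per-step probability that the path touched a
boundary between grid points), which removes the O(sqrt(dt)) first-passage
bias of the naive scheme; crossing times are jittered uniformly within the
step.  LBA trials are sampled exactly from the model's closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import CUES, DUMMY_CUE, SESSIONS, TrialTable
from .ddm import DDMCoreParams
from .lba import LBAParams

_COLUMNS = ["subject", "session", "block", "cue", "direction", "response",
            "correct", "rt_ms", "responded", "feedback"]


def _feedback(cue: str, responded: np.ndarray, correct: np.ndarray,
              rt_s: np.ndarray) -> np.ndarray:
    """Task feedback labels; cosmetic only (the 400 ms 'in time' rule)."""
    out = np.where(responded,
                   np.where(correct, "correct", "incorrect"),
                   "no_response").astype(object)
    if cue == "speed":
        out[responded & (rt_s < 0.4)] = "in_time"
        out[responded & (rt_s >= 0.4)] = "too_late"
    return out


def _assemble(subject, session, block, cue, rt_s, correct, responded,
              rng) -> pd.DataFrame:
    n = len(rt_s)
    direction = np.where(rng.random(n) < 0.5, "left", "right").astype(object)
    opposite = np.where(direction == "left", "right", "left")
    response = np.where(responded, np.where(correct, direction, opposite),
                        "none").astype(object)
    return pd.DataFrame({
        "subject": subject, "session": session, "block": block, "cue": cue,
        "direction": direction, "response": response,
        "correct": np.where(responded, correct, False),
        "rt_ms": np.where(responded, rt_s * 1000.0, np.nan),
        "responded": responded,
        "feedback": _feedback(cue, responded, correct, rt_s),
    }, columns=_COLUMNS)


def simulate_ddm_trials(p: DDMCoreParams, n: int, deadline: float = 1.0,
                        seed: int | np.random.Generator = 0,
                        dt: float = 1e-3, subject="s0", session="placebo",
                        cue="accuracy", block: int = 1) -> pd.DataFrame:
    """Simulate n diffusion trials as a trial-table fragment.

    RT = decision time + ter; trials whose RT would exceed ``deadline``
    (or that have not been absorbed by then) are marked non-responses.
    Bridge-corrected Euler scheme; identical output for identical seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rt = np.full(n, np.nan)
    hit_upper = np.zeros(n, dtype=bool)
    if n > 0:
        drift = np.full(n, p.v) if p.eta == 0 else rng.normal(p.v, p.eta, n)
        ter = np.full(n, p.ter) if p.st0 == 0 else \
            rng.uniform(p.ter - p.st0 / 2, p.ter + p.st0 / 2, n)
        x = np.full(n, p.z)
        active = np.arange(n)
        t = 0.0
        sqdt = np.sqrt(dt)
        max_decision = deadline  # no absorption after the response window
        s2dt = p.s ** 2 * dt
        while active.size and t < max_decision:
            x0 = x[active]
            x1 = x0 + drift[active] * dt + p.s * sqdt * rng.standard_normal(active.size)
            up = x1 >= p.a
            dn = x1 <= 0.0
            inside = ~(up | dn)
            if np.any(inside):
                # Brownian-bridge probability of an unseen boundary touch
                pu = np.exp(-2.0 * np.maximum(p.a - x0[inside], 0)
                            * np.maximum(p.a - x1[inside], 0) / s2dt)
                pd_ = np.exp(-2.0 * np.maximum(x0[inside], 0)
                             * np.maximum(x1[inside], 0) / s2dt)
                u = rng.random(inside.sum())
                bu = u < pu
                bd = (~bu) & (u < pu + pd_)
                up[inside] |= bu
                dn[inside] |= bd
            crossed = up | dn
            if np.any(crossed):
                idx = active[crossed]
                rt[idx] = t + dt * rng.random(idx.size)
                hit_upper[idx] = up[crossed]
            x[active] = x1
            active = active[~crossed]
            t += dt
        rt = rt + ter
    responded = np.isfinite(rt) & (rt <= deadline)
    rt = np.where(responded, rt, np.nan)
    return _assemble(subject, session, block, cue, rt, hit_upper, responded, rng)


def simulate_lba_trials(p: LBAParams, cell: tuple, n: int,
                        deadline: float = 1.0,
                        seed: int | np.random.Generator = 0,
                        subject="s0", block: int = 1) -> pd.DataFrame:
    """Simulate n LBA races for one (session, cue) cell.

    Uniform start points on [0, A], normal drift rates; the faster
    accumulator wins.  Races where both sampled rates are negative, and
    races finishing after the deadline, are non-responses.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    session, cue = cell
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = p.b[cell]
    starts = rng.uniform(0.0, p.A, size=(n, 2)) if p.A > 0 else np.zeros((n, 2))
    drifts = rng.normal([p.v_correct, p.v_error], p.s_drift, size=(n, 2)) \
        if p.s_drift > 0 else np.tile([p.v_correct, p.v_error], (n, 1))
    with np.errstate(divide="ignore"):
        ttf = np.where(drifts > 0, (b - starts) / drifts, np.inf)
    winner = np.argmin(ttf, axis=1)
    dtime = np.min(ttf, axis=1)
    rt = p.t0 + dtime
    responded = np.isfinite(dtime) & (rt <= deadline)
    correct = winner == 0
    rt = np.where(responded, rt, np.nan)
    return _assemble(subject, session, block, cue, rt, correct, responded, rng)


# ---------------------------------------------------------------------------
# full-study generator

@dataclass
class StudyConfig:
    """Configuration of a synthetic two-session, two-cue study.

    Population parameter means/SDs are chosen so summary statistics fall in
    the task's regime (speed RTs below accuracy RTs, accuracy rates in the
    70-95% band).  ``cue_effect_on_threshold`` multiplies the threshold on
    speed-cue trials; ``drug_effect_on_threshold`` multiplies thresholds in
    the drug session (1.0 = no effect, the study's conclusion and the
    default).
    """

    n_subjects: int = 20
    trials_per_cue_per_session: int = 100
    n_blocks: int = 2
    dummy_per_block: int = 5
    generator: str = "ddm"          # {"ddm", "lba"}
    deadline: float = 1.0           # response window (s)
    cue_effect_on_threshold: float = 0.6
    drug_effect_on_threshold: float = 1.0
    drug_effect_sd: float = 0.0     # between-subject SD of the drug multiplier
    seed: int = 0
    ddm_population: dict = field(default_factory=lambda: {
        "a_mean": 0.16, "a_sd": 0.03,        # accuracy-cue boundary separation
        "ter_mean": 0.30, "ter_sd": 0.03,
        "v_mean": 0.15, "v_sd": 0.04,
        "eta": 0.0, "s": 0.1,
    })
    lba_population: dict = field(default_factory=lambda: {
        "b_mean": 1.6, "b_sd": 0.15,         # accuracy-cue threshold
        "A_mean": 0.8, "A_sd": 0.1,
        "vc_mean": 3.0, "vc_sd": 0.3,
        "ve_mean": 1.5, "ve_sd": 0.2,
        "t0_mean": 0.25, "t0_sd": 0.03,
        "s_drift": 1.0,
    })
    trait_covariates: dict = field(default_factory=lambda: {
        "bis": {"mean": 19.0, "sd": 4.0},
        "bas": {"mean": 40.0, "sd": 5.0},
        "barratt": {"mean": 62.0, "sd": 10.0},
    })
    trait_effect_correlation: float = 0.0
    ddm_dt: float = 1e-3

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        base = cls()
        known = {}
        for k, v in d.items():
            if k not in cls.__dataclass_fields__:
                raise ValueError(f"unknown StudyConfig field {k!r}")
            if isinstance(getattr(base, k), dict):
                merged = dict(getattr(base, k))
                merged.update(v)
                known[k] = merged
            else:
                known[k] = v
        return cls(**known)

    def validate(self):
        if self.n_subjects < 1 or self.trials_per_cue_per_session < 1:
            raise ValueError("counts must be >= 1")
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")
        if self.generator not in ("ddm", "lba"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if not 0 < self.cue_effect_on_threshold <= 1:
            raise ValueError("cue_effect_on_threshold must be in (0, 1]")
        if self.trials_per_cue_per_session % self.n_blocks:
            raise ValueError("trials_per_cue_per_session must divide evenly "
                             "into blocks")


def _truncate_positive(value: float, floor: float = 1e-3) -> float:
    return max(value, floor)


def _subject_params(cfg: StudyConfig, rng: np.random.Generator) -> dict:
    if cfg.generator == "ddm":
        pop = cfg.ddm_population
        return {
            "a": _truncate_positive(rng.normal(pop["a_mean"], pop["a_sd"]), 0.06),
            "ter": _truncate_positive(rng.normal(pop["ter_mean"], pop["ter_sd"]), 0.1),
            "v": _truncate_positive(rng.normal(pop["v_mean"], pop["v_sd"]), 0.02),
            "eta": pop["eta"], "s": pop["s"],
        }
    pop = cfg.lba_population
    A = _truncate_positive(rng.normal(pop["A_mean"], pop["A_sd"]), 0.1)
    vc = _truncate_positive(rng.normal(pop["vc_mean"], pop["vc_sd"]), 0.5)
    ve = min(_truncate_positive(rng.normal(pop["ve_mean"], pop["ve_sd"]), 0.1),
             0.9 * vc)
    return {
        "b": max(_truncate_positive(rng.normal(pop["b_mean"], pop["b_sd"]), 0.2),
                 A + 0.05),
        "A": A, "vc": vc, "ve": ve,
        "t0": _truncate_positive(rng.normal(pop["t0_mean"], pop["t0_sd"]), 0.05),
        "s_drift": pop["s_drift"],
    }


def generate_study(cfg: StudyConfig) -> TrialTable:
    """Generate a full synthetic study as a validated trial table.

    Per subject: parameters drawn from the population distributions, two
    sessions by two cues with the configured trial counts split into
    blocks, dummy trials labelled for removal by preprocessing, and trait
    covariates correlated (as configured) with the subject's drug effect.
    Metadata records the full config and seed for bit-exact regeneration.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    frames = []
    traits_rows = []
    per_block = cfg.trials_per_cue_per_session // cfg.n_blocks
    for i in range(cfg.n_subjects):
        sid = f"s{i:02d}"
        rng = np.random.default_rng(subject_seeds[i])
        params = _subject_params(cfg, rng)
        drug_mult = cfg.drug_effect_on_threshold if cfg.drug_effect_sd == 0 else \
            max(rng.normal(cfg.drug_effect_on_threshold, cfg.drug_effect_sd), 0.1)
        z_effect = ((drug_mult - cfg.drug_effect_on_threshold) / cfg.drug_effect_sd
                    if cfg.drug_effect_sd > 0 else rng.standard_normal())
        rho = cfg.trait_effect_correlation
        row = {"subject": sid}
        for name, dist in cfg.trait_covariates.items():
            z = rho * z_effect + np.sqrt(max(1 - rho ** 2, 0)) * rng.standard_normal()
            row[name] = dist["mean"] + dist["sd"] * z
        traits_rows.append(row)
        for session in SESSIONS:
            mult = drug_mult if session == "drug" else 1.0
            for block in range(1, cfg.n_blocks + 1):
                for cue in CUES:
                    thr_mult = mult * (cfg.cue_effect_on_threshold
                                       if cue == "speed" else 1.0)
                    if cfg.generator == "ddm":
                        a = params["a"] * thr_mult
                        core = DDMCoreParams(a=a, z=a / 2, v=params["v"],
                                             ter=params["ter"], eta=params["eta"],
                                             s=params["s"])
                        frames.append(simulate_ddm_trials(
                            core, per_block, cfg.deadline, rng, dt=cfg.ddm_dt,
                            subject=sid, session=session, cue=cue, block=block))
                    else:
                        b = max(params["b"] * thr_mult, params["A"] + 0.01)
                        lba_p = LBAParams(
                            b={(session, cue): b}, A=params["A"],
                            v_correct=params["vc"], v_error=params["ve"],
                            t0=params["t0"], s_drift=params["s_drift"])
                        frames.append(simulate_lba_trials(
                            lba_p, (session, cue), per_block, cfg.deadline,
                            rng, subject=sid, block=block))
                if cfg.dummy_per_block:
                    nd = cfg.dummy_per_block
                    frames.append(pd.DataFrame({
                        "subject": np.repeat(sid, nd),
                        "session": np.repeat(session, nd),
                        "block": np.repeat(block, nd),
                        "cue": np.repeat(DUMMY_CUE, nd),
                        "direction": np.repeat("none", nd),
                        "response": np.repeat("none", nd),
                        "correct": np.zeros(nd, dtype=bool),
                        "rt_ms": np.full(nd, np.nan),
                        "responded": np.zeros(nd, dtype=bool),
                        "feedback": np.repeat("fixation", nd),
                    }, columns=_COLUMNS))
    df = pd.concat(frames, ignore_index=True)
    metadata = {
        "config": json.loads(json.dumps(cfg.to_dict())),
        "seed": cfg.seed,
        "generator": cfg.generator,
        "traits": traits_rows,
    }
    return TrialTable(df, metadata)


def study_traits(table: TrialTable) -> pd.DataFrame:
    """Per-subject trait covariates recorded by the generator."""
    rows = table.metadata.get("traits")
    if not rows:
        raise ValueError("table metadata carries no trait covariates")
    return pd.DataFrame(rows).set_index("subject")
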