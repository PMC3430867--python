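"""Linear ballistic accumulator: defective densities and maximum-likelihood fit.

Two independent linear accumulators race toward a threshold b.  Each starts
at a point drawn uniformly on [0, A] and rises at a rate drawn (per trial)
from a normal distribution; the accumulator matching the stimulus has mean
rate v_correct, the other v_error, with common SD s_drift (fixed at 1 for
identifiability).  The first accumulator to reach b determines the response;
non-decision time t0 adds to the decision time.  Trials on which both
sampled rates are negative never finish and are treated as non-responses,
so defective densities are normalized by the probability that at least one
rate is positive.

A single model is fitted jointly to both sessions by maximum likelihood,
with the threshold free across the four cue-by-session cells and all other
parameters shared (8 free parameters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .data_model import CUES, SESSIONS, TrialTable

#: density floor inside the log-likelihood
DENSITY_FLOOR = 1e-10

CELLS = tuple((session, cue) for session in SESSIONS for cue in CUES)

DEFAULT_BOUNDS = {
    "k": (0.01, 5.0),      # b - A
    "A": (0.01, 5.0),
    "v_correct": (0.0, 10.0),
    "v_ratio": (0.0, 1.0),  # v_error / v_correct
    "t0": (0.05, 0.6),
}


class ParameterError(ValueError):
    """LBA parameters violate their invariants."""


@dataclass(frozen=True)
class LBAParams:
    """LBA parameter set with one threshold per (session, cue) cell."""

    b: Mapping[tuple, float]    # keys (session, cue)
    A: float
    v_correct: float
    v_error: float
    t0: float
    s_drift: float = 1.0

    def __post_init__(self):
        if self.A < 0 or self.s_drift <= 0 or self.t0 < 0:
            raise ParameterError("need A >= 0, s_drift > 0, t0 >= 0")
        for cell, b in self.b.items():
            if b < self.A:
                raise ParameterError(f"threshold b={b} below A={self.A} in cell {cell}")
        if self.v_error >= self.v_correct:
            raise ParameterError("convention requires v_correct > v_error")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["b"] = {f"{s}/{c}": v for (s, c), v in self.b.items()}
        return d


@dataclass
class LBAFit:
    params: LBAParams
    loglik: float
    n_eval: int
    converged: bool
    restarts: int
    seed: int
    n_floored: int = 0

    def to_json(self) -> str:
        d = {"params": self.params.to_dict(), "loglik": self.loglik,
             "n_eval": self.n_eval, "converged": self.converged,
             "restarts": self.restarts, "seed": self.seed,
             "n_floored": self.n_floored}
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# single-accumulator first-passage functions (decision time t, no t0)

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _npdf(x):
    return np.exp(-0.5 * x * x) / _SQRT2PI


def _acc_cdf(t, b, A, v, s):
    """P(accumulator crosses b by time t), start ~ U[0,A], rate ~ N(v, s)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    ts = tp * s
    if A < 1e-10:
        out[pos] = ndtr((tp * v - b) / ts)
        return out
    g1 = (b - A - tp * v) / ts
    g2 = (b - tp * v) / ts
    out[pos] = (1.0
                + (b - A - tp * v) / A * ndtr(g1)
                - (b - tp * v) / A * ndtr(g2)
                + ts / A * (_npdf(g1) - _npdf(g2)))
    return np.clip(out, 0.0, 1.0)


def _acc_pdf(t, b, A, v, s):
    """First-passage density of one accumulator through b."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    tp = t[pos]
    ts = tp * s
    if A < 1e-10:
        out[pos] = _npdf((tp * v - b) / ts) * b / (s * tp ** 2)
        return out
    g1 = (b - A - tp * v) / ts
    g2 = (b - tp * v) / ts
    out[pos] = (-v * ndtr(g1) + s * _npdf(g1)
                + v * ndtr(g2) - s * _npdf(g2)) / A
    return np.maximum(out, 0.0)


def response_probability_normalizer(p: LBAParams) -> float:
    """P(at least one accumulator has positive rate) = 1 - Phi(-vc/s)Phi(-ve/s)."""
    return 1.0 - ndtr(-p.v_correct / p.s_drift) * ndtr(-p.v_error / p.s_drift)


def lba_defective_density(t, winner: str, cell: tuple, p: LBAParams) -> np.ndarray:
    """Defective density of total RT ``t`` for ``winner`` in ``cell``.

    Zero for t <= t0; the densities of both winners jointly integrate to 1
    (the normalizer excludes races where both sampled rates are negative,
    which end in non-response).
    """
    if winner not in ("correct", "error"):
        raise ValueError(f"winner must be 'correct' or 'error', got {winner!r}")
    b = p.b[cell]
    td = np.asarray(t, dtype=float) - p.t0
    vw, vl = ((p.v_correct, p.v_error) if winner == "correct"
              else (p.v_error, p.v_correct))
    dens = _acc_pdf(td, b, p.A, vw, p.s_drift) * \
        (1.0 - _acc_cdf(td, b, p.A, vl, p.s_drift))
    return dens / response_probability_normalizer(p)


def lba_defective_cdf(t, winner: str, cell: tuple, p: LBAParams,
                      n_grid: int = 2048) -> np.ndarray:
    """Defective CDF of total RT for ``winner``, by numeric integration."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tmax = max(float(np.max(t)), p.t0 + 1.0)
    grid = np.linspace(p.t0, tmax, n_grid)
    f = lba_defective_density(grid, winner, cell, p)
    dx = np.diff(grid)
    c = np.concatenate([[0.0], np.cumsum(0.5 * dx * (f[1:] + f[:-1]))])
    return np.interp(t, grid, c, left=0.0)


def _prepare_cells(trials: TrialTable) -> dict:
    """Per-cell correct/error RT arrays (seconds) for fast likelihood evals."""
    df = trials.df
    data = {}
    for cell in CELLS:
        session, cue = cell
        sub = df[(df["session"] == session) & (df["cue"] == cue)]
        rt = sub["rt_ms"].to_numpy(dtype=float) / 1000.0
        correct = sub["correct"].to_numpy(dtype=bool)
        data[cell] = (rt[correct], rt[~correct])
    return data


def _loglik_cells(data: dict, p: LBAParams) -> tuple[float, int]:
    total = 0.0
    n_floored = 0
    for cell, (rt_c, rt_e) in data.items():
        for winner, rt in (("correct", rt_c), ("error", rt_e)):
            if rt.size == 0:
                continue
            d = lba_defective_density(rt, winner, cell, p)
            n_floored += int((d < DENSITY_FLOOR).sum())
            total += float(np.sum(np.log(np.maximum(d, DENSITY_FLOOR))))
    return total, n_floored


def lba_log_likelihood(trials: TrialTable, p: LBAParams) -> tuple[float, int]:
    """Summed log defective density over preprocessed trials.

    Returns ``(loglik, n_floored)`` where ``n_floored`` counts trials whose
    density fell below the floor (e.g. RT <= t0).
    """
    return _loglik_cells(_prepare_cells(trials), p)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class LBAFitConfig:
    n_restarts: int = 5
    seed: int = 0
    maxiter: int = 4000
    xatol: float = 1e-5
    fatol: float = 1e-7
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    @classmethod
    def from_dict(cls, d: Mapping) -> "LBAFitConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)


def _vector_to_params(x: np.ndarray) -> LBAParams:
    # x = [k_dr_sp, k_dr_ac, k_pl_sp, k_pl_ac, A, v_correct, v_ratio, t0]
    A = float(x[4])
    vc = float(x[5])
    ve = float(x[6]) * vc
    b = {cell: A + float(k) for cell, k in zip(CELLS, x[:4])}
    return LBAParams(b=b, A=A, v_correct=vc, v_error=min(ve, vc * (1 - 1e-9)),
                     t0=float(x[7]))


def _bounds_list(cfg: LBAFitConfig):
    b = cfg.bounds
    return [b["k"]] * 4 + [b["A"], b["v_correct"],
                           (b["v_ratio"][0], min(b["v_ratio"][1], 1.0 - 1e-6)),
                           b["t0"]]


def _to_box(u, bounds):
    lo = np.array([x[0] for x in bounds])
    hi = np.array([x[1] for x in bounds])
    return lo + (hi - lo) * expit(np.asarray(u))


def _from_box(x, bounds):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return logit(np.clip((np.asarray(x) - lo) / (hi - lo), 1e-6, 1 - 1e-6))


def fit_lba(trials: TrialTable, config: LBAFitConfig | None = None) -> LBAFit:
    """Maximum-likelihood fit of the single joint LBA model.

    The threshold is free per (session, cue) cell; A, drift means and t0
    are shared; s_drift is fixed at 1.  Nelder-Mead under a logistic box
    transform with seeded random restarts; deterministic given the seed.
    """
    cfg = config or LBAFitConfig()
    for session in SESSIONS:
        for cue in CUES:
            if len(trials.df[(trials.df["session"] == session)
                             & (trials.df["cue"] == cue)]) == 0:
                raise ValueError(f"missing cell ({session}, {cue}) in data")
    bounds = _bounds_list(cfg)
    rng = np.random.default_rng(cfg.seed)
    data = _prepare_cells(trials)
    n_eval = 0

    def objective(u):
        nonlocal n_eval
        n_eval += 1
        try:
            params = _vector_to_params(_to_box(u, bounds))
        except ParameterError:
            return 1e12
        ll, _ = _loglik_cells(data, params)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def _heuristic_start() -> np.ndarray:
        """Moment-based start: t0 near the fastest RT, thresholds from
        median decision times at a nominal drift."""
        all_rt = np.concatenate([np.concatenate(v) for v in data.values()
                                 if sum(x.size for x in v)])
        t0_0 = float(np.clip(0.9 * np.min(all_rt), *bounds[7]))
        A0, vc0 = 1.0, 3.0
        ks = []
        for cell in CELLS:
            rt_c, rt_e = data[cell]
            med = float(np.median(np.concatenate([rt_c, rt_e])))
            ks.append(np.clip(vc0 * max(med - t0_0, 0.02) - A0 / 2, *bounds[0]))
        return np.array(ks + [A0, vc0, 0.5, t0_0])

    opts = {"maxiter": cfg.maxiter, "xatol": cfg.xatol, "fatol": cfg.fatol}
    best = None
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [_heuristic_start()] + [
        lo + (hi - lo) * rng.uniform(0.15, 0.85, size=len(bounds))
        for _ in range(max(cfg.n_restarts - 1, 0))]
    for x0 in starts:
        res = minimize(objective, _from_box(x0, bounds),
                       method="Nelder-Mead", options=opts)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError("LBA objective non-finite at every restart")
    # iterated polish: re-seed the simplex at the incumbent optimum until
    # no further improvement (guards against premature simplex collapse)
    for _ in range(3):
        prev = best.fun
        res = minimize(objective, best.x, method="Nelder-Mead", options=opts)
        if res.fun < best.fun:
            best = res
        if prev - res.fun < 1e-6:
            break
    params = _vector_to_params(_to_box(best.x, bounds))
    ll, n_floored = lba_log_likelihood(trials, params)
    return LBAFit(params=params, loglik=ll, n_eval=n_eval,
                  converged=bool(best.success), restarts=cfg.n_restarts,
                  seed=cfg.seed, n_floored=n_floored)
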