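"""Drift diffusion model: first-passage densities and chi-square quantile fitting.

The Wiener diffusion accumulates evidence from a starting point z between
absorbing boundaries at 0 (error) and a (correct, for positive drift v),
with diffusion coefficient s (classically fixed at 0.1).  First-passage
densities are evaluated with the standard dual infinite-series
representation: a small-time expansion (image method) and a large-time
expansion (eigenfunction series), switching per time point to whichever
needs fewer terms for a target truncation error.  Across-trial drift
variability (eta) is integrated out by Gauss-Hermite quadrature.

Fitting follows the quantile chi-square method: observed defective bin
masses, delimited by the 5 RT quantiles of correct and error responses, are
compared to model-implied bin probabilities, and the chi-square discrepancy
is minimized with a Nelder-Mead simplex under a box transform, with seeded
random restarts.  Threshold (boundary separation) and non-decision time are
free per cue (speed vs. accuracy); drift, drift variability and the
relative starting point are shared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, roots_hermite

from .data_model import CUES, QuantileSummary

#: truncation error target for the first-passage series
SERIES_EPS = 1e-7
#: expected-probability floor inside the chi-square
P_EXP_FLOOR = 1e-5
#: default Gauss-Hermite node count for drift-variability integration
GH_NODES = 20

DEFAULT_BOUNDS = {
    "a": (0.05, 0.40),
    "ter": (0.10, 0.60),
    "v": (0.0, 0.60),
    "eta": (0.0, 0.30),
}


class ParameterError(ValueError):
    """Diffusion parameters violate their invariants."""


@dataclass(frozen=True)
class DDMCoreParams:
    """Single-condition diffusion parameters.

    a: boundary separation; z: starting point (0 < z < a); v: mean drift;
    eta: across-trial SD of drift; ter: non-decision time (s); st0:
    across-trial range of ter; s: diffusion coefficient (scaling constant).
    """

    a: float
    z: float
    v: float
    ter: float
    eta: float = 0.0
    st0: float = 0.0
    s: float = 0.1

    def __post_init__(self):
        if not (self.a > 0 and 0 < self.z < self.a):
            raise ParameterError(f"need 0 < z < a, got z={self.z}, a={self.a}")
        if self.ter < 0 or self.eta < 0 or self.st0 < 0 or self.s <= 0:
            raise ParameterError("ter, eta, st0 must be >= 0 and s > 0")


@dataclass(frozen=True)
class DDMSessionParams:
    """Per-session parameter set with cue-specific threshold and Ter."""

    a_speed: float
    a_accuracy: float
    ter_speed: float
    ter_accuracy: float
    v: float
    eta: float = 0.0
    st0: float = 0.0
    z_ratio: float = 0.5
    s: float = 0.1

    def core(self, cue: str) -> DDMCoreParams:
        a = {"speed": self.a_speed, "accuracy": self.a_accuracy}[cue]
        ter = {"speed": self.ter_speed, "accuracy": self.ter_accuracy}[cue]
        return DDMCoreParams(a=a, z=self.z_ratio * a, v=self.v, ter=ter,
                             eta=self.eta, st0=self.st0, s=self.s)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DDMFit:
    """Result of a chi-square quantile fit for one session."""

    params: DDMSessionParams
    chi2: float
    n_eval: int
    converged: bool
    restarts: int
    seed: int

    def to_json(self) -> str:
        d = {"params": self.params.to_dict(), "chi2": self.chi2,
             "n_eval": self.n_eval, "converged": self.converged,
             "restarts": self.restarts, "seed": self.seed}
        return json.dumps(d, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# first-passage series (unit diffusion, scaled time u = t / a^2)

def _ftt_small(u: np.ndarray, w: float, kmax: int) -> np.ndarray:
    ks = np.arange(-kmax, kmax + 1)
    arg = w + 2.0 * ks[:, None]
    out = np.sum(arg * np.exp(-arg ** 2 / (2.0 * u[None, :])), axis=0)
    return out / np.sqrt(2.0 * np.pi * u ** 3)


def _ftt_large(u: np.ndarray, w: float, kmax: int) -> np.ndarray:
    ks = np.arange(1, kmax + 1)
    out = np.sum(ks[:, None] * np.exp(-ks[:, None] ** 2 * np.pi ** 2 * u[None, :] / 2.0)
                 * np.sin(ks[:, None] * np.pi * w), axis=0)
    return np.pi * out


def _fpt_density_lower_unit(t: np.ndarray, a: float, v: float, w: float,
                            eps: float = SERIES_EPS) -> np.ndarray:
    """Density of absorption at the lower boundary, unit diffusion."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if not np.any(pos):
        return out
    u = t[pos] / a ** 2
    # per-point term counts (truncation bound of the dual series)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = np.where(2.0 * np.sqrt(2.0 * np.pi * u) * eps < 1.0,
                      2.0 + np.sqrt(np.maximum(
                          -2.0 * u * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * u)), 0.0)),
                      2.0)
        ks = np.maximum(ks, np.sqrt(u) + 1.0)
        kl = np.where(np.pi * u * eps < 1.0,
                      np.sqrt(np.maximum(-2.0 * np.log(np.pi * u * eps), 0.0)
                              / (np.pi ** 2 * u)),
                      1.0 / (np.pi * np.sqrt(u)))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(u)))
    small = ks < kl
    f = np.zeros_like(u)
    if np.any(small):
        kmax = min(int(np.ceil(ks[small].max() / 2.0)) + 1, 80)
        f[small] = _ftt_small(u[small], w, kmax)
    if np.any(~small):
        kmax = min(int(np.ceil(kl[~small].max())) + 1, 500)
        f[~small] = _ftt_large(u[~small], w, kmax)
    out[pos] = np.maximum(
        f * np.exp(-v * a * w - v ** 2 * t[pos] / 2.0) / a ** 2, 0.0)
    return out


def _gh_drifts(p: DDMCoreParams):
    """Gauss-Hermite nodes/weights over the trial-drift distribution."""
    if p.eta == 0:
        return np.array([p.v]), np.array([1.0])
    x, wts = roots_hermite(GH_NODES)
    return p.v + np.sqrt(2.0) * p.eta * x, wts / np.sqrt(np.pi)


def wiener_fpt_density(t, boundary: str, p: DDMCoreParams) -> np.ndarray:
    """Defective first-passage density at ``boundary`` for decision time t.

    ``t`` is decision time in seconds (non-decision time excluded); the
    density is 0 for t <= 0 and integrates, over both boundaries jointly,
    to 1.  ``boundary`` is ``"correct"`` (upper, reached by positive drift)
    or ``"error"`` (lower).
    """
    if boundary not in ("correct", "error"):
        raise ValueError(f"boundary must be 'correct' or 'error', got {boundary!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    a1, w = p.a / p.s, p.z / p.a
    drifts, wts = _gh_drifts(p)
    out = np.zeros_like(t)
    for v, wt in zip(drifts, wts):
        v1 = v / p.s
        if boundary == "correct":  # upper boundary: reflect
            out += wt * _fpt_density_lower_unit(t, a1, -v1, 1.0 - w)
        else:
            out += wt * _fpt_density_lower_unit(t, a1, v1, w)
    return out


def _decay_rate(p: DDMCoreParams) -> float:
    """Slowest exponential decay rate of the first-passage density."""
    a1 = p.a / p.s
    return np.pi ** 2 / (2.0 * a1 ** 2) + (p.v / p.s) ** 2 / 2.0


def _horizon(p: DDMCoreParams) -> float:
    """Decision time beyond which the residual mass is negligible."""
    lam = _decay_rate(p)
    return float(np.clip(16.0 / max(lam, 1e-3), 2.0, 60.0))


def _density_grid(p: DDMCoreParams, tmax: float, n: int = 1536):
    grid = np.linspace(0.0, tmax, n)
    fc = wiener_fpt_density(grid, "correct", p)
    fe = wiener_fpt_density(grid, "error", p)
    return grid, fc, fe


def _cum_trapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    dx = np.diff(x)
    c = np.concatenate([[0.0], np.cumsum(0.5 * dx * (y[1:] + y[:-1]))])
    return c


def ddm_defective_cdf(t, boundary: str, p: DDMCoreParams,
                      n_grid: int = 4096) -> np.ndarray:
    """Defective CDF of decision time at ``boundary``.

    Computed by trapezoidal integration of the series density on a fine
    grid.  Nondecreasing in t; its limit as t grows is the boundary's
    choice probability, and the two limits sum to 1.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tmax = max(_horizon(p), float(np.max(t, initial=0.0)))
    grid = np.linspace(0.0, tmax, n_grid)
    f = wiener_fpt_density(grid, boundary, p)
    cdf = _cum_trapz(f, grid)
    return np.interp(t, grid, cdf, left=0.0)


def choice_probability(boundary: str, p: DDMCoreParams, n_grid: int = 4096) -> float:
    """Limiting probability of absorption at ``boundary`` (numeric)."""
    return float(ddm_defective_cdf(np.array([_horizon(p)]), boundary, p, n_grid)[0])


# ---------------------------------------------------------------------------
# quantile chi-square machinery

#: defective bin masses implied by the 5-quantile split of one response class
QUANTILE_BIN_MASS = np.array([0.1, 0.2, 0.2, 0.2, 0.2, 0.1])


def ddm_bin_probabilities(p: DDMSessionParams, cue: str,
                          correct_edges: Sequence[float],
                          error_edges: Sequence[float] | None,
                          n_grid: int = 1536) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied defective bin probabilities for one cue.

    Edges are observed RT quantiles on the total-RT scale (decision time
    plus non-decision time).  Returns ``(correct_bins, error_bins)`` with
    ``len(edges)+1`` bins per class, or a single collapsed error bin when
    ``error_edges`` is None (sparse errors).  The bins jointly sum to 1 up
    to integration tolerance.
    """
    core = p.core(cue)
    tmax = max(_horizon(core),
               float(np.max(np.asarray(correct_edges)) - core.ter + 0.5),
               0.5)
    if error_edges is not None and len(error_edges):
        tmax = max(tmax, float(np.max(np.asarray(error_edges)) - core.ter + 0.5))
    grid, fc, fe = _density_grid(core, tmax, n_grid)
    Fc, Fe = _cum_trapz(fc, grid), _cum_trapz(fe, grid)
    pc, pe = Fc[-1], Fe[-1]

    def bins(edges, F, total):
        td = np.clip(np.asarray(edges, dtype=float) - core.ter, 0.0, None)
        cdf = np.interp(td, grid, F, left=0.0)
        cdf = np.concatenate([[0.0], cdf, [total]])
        return np.maximum(np.diff(cdf), 0.0)

    correct_bins = bins(correct_edges, Fc, pc)
    if error_edges is None:
        error_bins = np.array([pe])
    else:
        error_bins = bins(error_edges, Fe, pe)
    return correct_bins, error_bins


def observed_bin_masses(summary: QuantileSummary) -> tuple[np.ndarray, np.ndarray]:
    """Observed defective bin masses implied by a quantile summary."""
    correct = summary.p_correct * QUANTILE_BIN_MASS
    if summary.error_quantiles is None:
        error = np.array([1.0 - summary.p_correct])
    else:
        error = (1.0 - summary.p_correct) * QUANTILE_BIN_MASS
    return correct, error


def chi_square_statistic(n: int, p_obs, p_exp,
                         floor: float = P_EXP_FLOOR) -> float:
    """N-weighted chi-square discrepancy between two bin-mass vectors."""
    p_obs = np.asarray(p_obs, dtype=float)
    p_exp = np.maximum(np.asarray(p_exp, dtype=float), floor)
    return n * float(np.sum((p_obs - p_exp) ** 2 / p_exp))


def ddm_chi_square(summaries: Mapping[str, QuantileSummary],
                   p: DDMSessionParams, n_grid: int = 1536) -> float:
    """Chi-square discrepancy between observed and model bin masses.

    ``summaries`` maps cue -> QuantileSummary for one session.  For each
    cue, response class and bin the contribution is
    N * (p_obs - p_exp)^2 / p_exp with N the cue's trial count; expected
    probabilities are floored at ``P_EXP_FLOOR``.
    """
    chi2 = 0.0
    for cue in CUES:
        s = summaries[cue]
        exp_c, exp_e = ddm_bin_probabilities(
            p, cue, s.correct_quantiles,
            None if s.error_quantiles is None else s.error_quantiles,
            n_grid=n_grid)
        obs_c, obs_e = observed_bin_masses(s)
        chi2 += chi_square_statistic(s.n_trials,
                                     np.concatenate([obs_c, obs_e]),
                                     np.concatenate([exp_c, exp_e]))
    return chi2


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitConfig:
    """Configuration for seeded multi-restart Nelder-Mead fitting."""

    n_restarts: int = 5
    seed: int = 0
    fix_eta: bool = True
    maxiter: int = 2000
    xatol: float = 1e-4
    fatol: float = 1e-6
    n_grid: int = 1024
    bounds: dict = field(default_factory=lambda: {k: v for k, v in DEFAULT_BOUNDS.items()})

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitConfig":
        known = {k: d[k] for k in d if k in cls.__dataclass_fields__}
        return cls(**known)


_PARAM_NAMES = ("a_speed", "a_accuracy", "ter_speed", "ter_accuracy", "v", "eta")


def _param_bounds(cfg: FitConfig, fix_eta: bool) -> list[tuple[float, float]]:
    b = cfg.bounds
    bounds = [b["a"], b["a"], b["ter"], b["ter"], b["v"]]
    if not fix_eta:
        bounds.append(b["eta"])
    return bounds


def _to_box(u: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * expit(u)


def _from_box(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    frac = np.clip((x - lo) / (hi - lo), 1e-6, 1 - 1e-6)
    return logit(frac)


def _vector_to_params(x: np.ndarray, fix_eta: bool) -> DDMSessionParams:
    eta = 0.0 if fix_eta else float(x[5])
    return DDMSessionParams(a_speed=float(x[0]), a_accuracy=float(x[1]),
                            ter_speed=float(x[2]), ter_accuracy=float(x[3]),
                            v=float(x[4]), eta=eta)


def fit_ddm(summaries: Mapping[str, QuantileSummary],
            config: FitConfig | None = None) -> DDMFit:
    """Fit the diffusion model to one session's quantile summaries.

    Minimizes the quantile chi-square with Nelder-Mead under a logistic box
    transform, restarting from seeded uniform draws inside the parameter
    box and keeping the best optimum.  Deterministic given the seed.
    """
    cfg = config or FitConfig()
    bounds = _param_bounds(cfg, cfg.fix_eta)
    rng = np.random.default_rng(cfg.seed)
    n_eval = 0

    def objective(u):
        nonlocal n_eval
        n_eval += 1
        x = _to_box(np.asarray(u), bounds)
        try:
            params = _vector_to_params(x, cfg.fix_eta)
        except ParameterError:
            return 1e12
        return ddm_chi_square(summaries, params, n_grid=cfg.n_grid)

    best = None
    failures = []
    for _ in range(cfg.n_restarts):
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        x0 = lo + (hi - lo) * rng.uniform(0.15, 0.85, size=len(bounds))
        try:
            res = minimize(objective, _from_box(x0, bounds), method="Nelder-Mead",
                           options={"maxiter": cfg.maxiter, "xatol": cfg.xatol,
                                    "fatol": cfg.fatol})
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all restarts failed: {failures}")
    # iterated polish: re-seed the simplex at the incumbent optimum until
    # no further improvement (guards against premature simplex collapse)
    for _ in range(3):
        prev = best.fun
        res = minimize(objective, best.x, method="Nelder-Mead",
                       options={"maxiter": cfg.maxiter, "xatol": cfg.xatol,
                                "fatol": cfg.fatol})
        if res.fun < best.fun:
            best = res
        if prev - res.fun < 1e-6:
            break
    x = _to_box(best.x, bounds)
    return DDMFit(params=_vector_to_params(x, cfg.fix_eta),
                  chi2=float(best.fun), n_eval=n_eval,
                  converged=bool(best.success), restarts=cfg.n_restarts,
                  seed=cfg.seed)


def predicted_quantiles(p: DDMSessionParams, cue: str,
                        probs: Sequence[float],
                        n_grid: int = 2048) -> dict:
    """Model-implied defective RT quantiles for plotting against data."""
    core = p.core(cue)
    grid, fc, fe = _density_grid(core, _horizon(core), n_grid)
    Fc, Fe = _cum_trapz(fc, grid), _cum_trapz(fe, grid)
    out = {"p_correct": float(Fc[-1])}
    for name, F in (("correct", Fc), ("error", Fe)):
        total = F[-1]
        if total <= 0:
            out[name] = np.full(len(probs), np.nan)
            continue
        targets = np.asarray(probs) * total
        out[name] = core.ter + np.interp(targets, F, grid)
    return out
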