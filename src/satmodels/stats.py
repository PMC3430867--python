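"""Frequentist and default Bayesian tests for drug-effect inference.

Covers the paired t-test, the 2x2 within-subject (repeated measures) ANOVA,
a Pearson correlation screen with Bonferroni control, and the default
Bayesian one-sample t-test with a Cauchy prior on the standardized effect
size (the JZS prior, scale r = 1).  The Bayes factor BF01 is evaluated by
deterministic adaptive quadrature:

    BF01 = T_nu(t; 0) / integral T_nu(t; delta * sqrt(n)) Cauchy(delta; 0, r) d delta

where T_nu(.; ncp) is the noncentral-t density with nu = n - 1 degrees of
freedom.  With prior odds pi0/(1-pi0), the posterior plausibility of the
null is P(H0 | data) = pi0 BF01 / (pi0 BF01 + 1 - pi0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

#: default Cauchy prior scale on the standardized effect size
DEFAULT_R_SCALE = 1.0


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    mean_diff: float


@dataclass(frozen=True)
class BayesTTestResult:
    t: float
    n: int
    r_scale: float
    bf01: float
    posterior_h0: float
    prior_h0: float = 0.5


@dataclass(frozen=True)
class AnovaResult:
    """2x2 within-subject ANOVA: two main effects and their interaction."""

    factor_names: tuple
    F: dict          # name -> F statistic on (1, n-1) df
    p: dict
    df: tuple        # (1, n - 1)
    cell_means: np.ndarray
    ss: dict         # effect and error sums of squares


def paired_t_test(x, y) -> TTestResult:
    """Two-sided paired t-test of x against y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return TTestResult(t=0.0, df=len(d) - 1, p=1.0, mean_diff=0.0)
        raise ValueError("differences have zero variance; t undefined")
    res = stats.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=len(x) - 1,
                       p=float(res.pvalue), mean_diff=float(np.mean(d)))


def one_sample_t(x) -> TTestResult:
    """Two-sided one-sample t-test of x against zero."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a vector with n >= 2")
    if np.std(x, ddof=1) == 0:
        raise ValueError("zero variance; t undefined")
    res = stats.ttest_1samp(x, 0.0)
    return TTestResult(t=float(res.statistic), df=len(x) - 1,
                       p=float(res.pvalue), mean_diff=float(np.mean(x)))


def rm_anova_2x2(cells, factor_names=("factor1", "factor2")) -> AnovaResult:
    """Within-subject 2x2 ANOVA from an (n_subjects, 4) cell matrix.

    Column order is (A1B1, A1B2, A2B1, A2B2): the first factor varies
    slowest.  Each effect is tested against its own subject-by-effect
    interaction, giving F statistics on (1, n-1) degrees of freedom, the
    standard fully within-subject decomposition.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 2 or y.shape[1] != 4:
        raise ValueError("cells must be an (n_subjects, 4) matrix")
    if np.any(~np.isfinite(y)):
        raise ValueError("missing cell values")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    yc = y.reshape(n, 2, 2)               # subject x A x B
    grand = yc.mean()
    subj = yc.mean(axis=(1, 2))           # per-subject means
    a_m = yc.mean(axis=(0, 2))            # A level means
    b_m = yc.mean(axis=(0, 1))
    ab_m = yc.mean(axis=0)                # A x B cell means
    sa = yc.mean(axis=2)                  # subject x A
    sb = yc.mean(axis=1)                  # subject x B

    ss_a = 2 * n * np.sum((a_m - grand) ** 2)
    ss_b = 2 * n * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((sa - subj[:, None] - a_m[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((sb - subj[:, None] - b_m[None, :] + grand) ** 2)
    resid = (yc - sa[:, :, None] - sb[:, None, :] - ab_m[None, :, :]
             + subj[:, None, None] + a_m[None, :, None] + b_m[None, None, :]
             - grand)
    ss_abs = np.sum(resid ** 2)

    dfe = n - 1
    names = (factor_names[0], factor_names[1],
             f"{factor_names[0]}x{factor_names[1]}")
    eff_ss = {names[0]: (ss_a, ss_as), names[1]: (ss_b, ss_bs),
              names[2]: (ss_ab, ss_abs)}
    F, p, ss = {}, {}, {}
    for name, (ss_eff, ss_err) in eff_ss.items():
        ms_err = ss_err / dfe
        F[name] = float(ss_eff / ms_err) if ms_err > 0 else 0.0
        p[name] = float(stats.f.sf(F[name], 1, dfe)) if ms_err > 0 else 1.0
        ss[name] = {"effect": float(ss_eff), "error": float(ss_err)}
    return AnovaResult(factor_names=tuple(factor_names), F=F, p=p,
                       df=(1, dfe), cell_means=ab_m, ss=ss)


def jzs_bayes_factor_01(t: float, n: int, r_scale: float = DEFAULT_R_SCALE) -> float:
    """Bayes factor BF01 for the default one-sample Bayesian t-test.

    Null marginal: central t density at the observed statistic.  Alternative
    marginal: noncentral-t density averaged over the Cauchy(0, r) prior on
    the standardized effect size, by adaptive quadrature (relative tolerance
    1e-8).  BF01 > 1 favours the null.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    nu = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return (stats.nct.pdf(t, nu, delta * sqrt_n)
                * stats.cauchy.pdf(delta, 0.0, r_scale))

    alt, err = integrate.quad(integrand, -np.inf, np.inf,
                              epsrel=1e-8, epsabs=0, limit=400)
    if not np.isfinite(alt) or alt <= 0 or err > 1e-4 * alt:
        raise RuntimeError(f"quadrature failed: integral={alt}, error={err}")
    return float(stats.t.pdf(t, nu) / alt)


def posterior_prob_h0(bf01: float, prior_h0: float = 0.5) -> float:
    """Posterior plausibility of H0 given BF01 and the prior probability."""
    if bf01 <= 0:
        raise ValueError("bf01 must be positive")
    if not 0 < prior_h0 < 1:
        raise ValueError("prior_h0 must lie in (0, 1)")
    return prior_h0 * bf01 / (prior_h0 * bf01 + 1.0 - prior_h0)


def bayes_t_test_from_t(t: float, n: int, r_scale: float = DEFAULT_R_SCALE,
                        prior_h0: float = 0.5) -> BayesTTestResult:
    """Default Bayesian t-test summary from a t statistic and sample size."""
    bf01 = jzs_bayes_factor_01(t, n, r_scale)
    return BayesTTestResult(t=float(t), n=int(n), r_scale=r_scale, bf01=bf01,
                            posterior_h0=posterior_prob_h0(bf01, prior_h0),
                            prior_h0=prior_h0)


def bayes_t_test(diff, r_scale: float = DEFAULT_R_SCALE,
                 prior_h0: float = 0.5) -> BayesTTestResult:
    """Default Bayesian one-sample t-test on difference scores."""
    res = one_sample_t(diff)
    return bayes_t_test_from_t(res.t, len(np.asarray(diff)), r_scale, prior_h0)


def bonferroni_alpha(family_alpha: float, n_comparisons: int) -> float:
    """Per-comparison alpha after Bonferroni correction."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons


def correlation_screen(effects: pd.DataFrame, covariates: pd.DataFrame,
                       family_alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlations of each effect column with each covariate column.

    Returns a tidy frame with one row per (effect, covariate) pair: r, the
    two-sided p, the Bonferroni-corrected alpha for the whole family, and
    whether the pair passes it.  Zero-variance columns yield an undefined
    (NaN) correlation, flagged rather than raised.
    """
    if len(effects) != len(covariates):
        raise ValueError("effects and covariates must cover the same subjects")
    if len(effects) < 3:
        raise ValueError("need at least 3 subjects for a correlation screen")
    n_comp = effects.shape[1] * covariates.shape[1]
    alpha = bonferroni_alpha(family_alpha, n_comp)
    rows = []
    for ecol in effects.columns:
        for ccol in covariates.columns:
            x = effects[ecol].to_numpy(dtype=float)
            y = covariates[ccol].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r_val, p_val, undef = np.nan, np.nan, True
            else:
                r_val, p_val = stats.pearsonr(x, y)
                undef = False
            rows.append({"effect": ecol, "covariate": ccol,
                         "r": float(r_val) if not undef else np.nan,
                         "p": float(p_val) if not undef else np.nan,
                         "corrected_alpha": alpha,
                         "significant": bool(not undef and p_val < alpha),
                         "undefined": undef})
    return pd.DataFrame(rows)
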