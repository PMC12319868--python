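"""Fit indices (chi-square, CFI, RMSEA, SRMR) and nested-model comparison.

Conventions: the likelihood-ratio chi-square is 2(loglik_saturated -
loglik_model); RMSEA uses N - 1 in its denominator with a 90% confidence
interval obtained by inverting the noncentral chi-square distribution;
SRMR includes mean-structure residuals because every model here carries a
mean structure.  Cutoff labels follow common SEM reporting practice:
CFI > .97 good / .95-.97 acceptable; RMSEA < .05 good / .05-.08
acceptable; SRMR < .05 good / .05-.10 acceptable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .fiml import em_mvn
from .fit import FitResult

__all__ = [
    "FitIndices",
    "ComparisonResult",
    "compute_fit_indices",
    "chi_square_difference",
    "lrt_pvalue",
    "cfi_from_chi2",
    "rmsea_from_chi2",
    "invariance_decision",
]

def _label(index: str, value: float) -> str:
    if not np.isfinite(value):
        return "undefined"
    if index == "cfi":
        if value > 0.97:
            return "good"
        return "acceptable" if value >= 0.95 else "poor"
    hi = 0.08 if index == "rmsea" else 0.10
    if value < 0.05:
        return "good"
    return "acceptable" if value <= hi else "poor"


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    cfi: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    n: int
    labels: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = {k: _label(k, getattr(self, k)) for k in ("cfi", "rmsea", "srmr")}


def _rmsea_ci(chi2: float, df: int, n: int, level: float = 0.90) -> tuple[float, float]:
    """90% RMSEA CI by noncentral-chi-square inversion (bisection to 1e-8)."""
    if df <= 0 or n <= 1:
        return (np.nan, np.nan)
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2   # .95 and .05

    def solve(target: float) -> float:
        # find lambda with ncx2.cdf(chi2, df, lambda) = target
        if stats.chi2.cdf(chi2, df) < target:
            return 0.0
        hi = max(chi2, df) * 2 + 10.0
        while stats.ncx2.cdf(chi2, df, hi) > target:
            hi *= 2.0
            if hi > 1e8:
                break
        return float(optimize.brentq(
            lambda lam: stats.ncx2.cdf(chi2, df, lam) - target, 0.0, hi, xtol=1e-8))

    lam_lo, lam_hi = solve(lo_q), solve(hi_q)
    denom = df * (n - 1)
    return (float(np.sqrt(lam_lo / denom)), float(np.sqrt(lam_hi / denom)))


def _srmr(fit: FitResult) -> float:
    """Root mean square standardized residual over covariances and means.

    Sample-side moments are the saturated (EM) estimates, which reduce to
    ordinary sample moments on complete data.
    """
    obj = fit.objective
    if obj is None:
        return np.nan
    th = np.array([fit.estimates[lab] for lab in obj.labels])
    obj._set_theta(th)
    sq, cnt = 0.0, 0
    for g, pdata in enumerate(obj.data):
        s_mu, s_cov, _ = em_mvn(pdata)
        _, _, mu, sigma = obj._group_moments(g)
        sd = np.sqrt(np.maximum(np.diag(s_cov), 1e-12))
        p = pdata.p
        for i in range(p):
            for j in range(i + 1):
                sq += ((s_cov[i, j] - sigma[i, j]) / (sd[i] * sd[j])) ** 2
                cnt += 1
            sq += ((s_mu[i] - mu[i]) / sd[i]) ** 2
            cnt += 1
    return float(np.sqrt(sq / cnt))


def compute_fit_indices(fit: FitResult, baseline: FitResult | None = None) -> FitIndices:
    """Fit indices for a fitted model.

    The incremental-fit baseline is the independence model (free means and
    variances, zero covariances); its log-likelihood is computed in closed
    form during fitting, or an explicitly fitted baseline may be supplied.
    """
    if fit.loglik_saturated is None:
        raise ValueError("fit lacks a saturated log-likelihood (compute_baselines=False?)")
    flags: list[str] = []
    n = fit.n_total
    chi2 = 2.0 * (fit.loglik_saturated - fit.loglik)
    if chi2 < 0:
        if chi2 < -1e-4 * max(1.0, abs(fit.loglik)):
            warnings.warn(f"negative chi-square {chi2:.4g} clamped to 0", stacklevel=2)
            flags.append("chi2_clamped")
        chi2 = 0.0
    df = fit.df
    if baseline is not None:
        chi2_b = 2.0 * (fit.loglik_saturated - baseline.loglik)
        df_b = baseline.df
    else:
        chi2_b = 2.0 * (fit.loglik_saturated - fit.loglik_independence)
        df_b = fit.spec.n_moments - fit.q_independence
    if df == 0:
        flags.append("df_zero")
        p, cfi, rmsea, ci = 1.0, 1.0, np.nan, (np.nan, np.nan)
    else:
        p = lrt_pvalue(chi2, df)
        cfi = cfi_from_chi2(chi2, df, chi2_b, df_b)
        rmsea = rmsea_from_chi2(chi2, df, n)
        ci = _rmsea_ci(chi2, df, n)
    return FitIndices(chi2=float(chi2), df=df, p=p, cfi=float(cfi), rmsea=rmsea,
                      rmsea_ci=ci, srmr=_srmr(fit), n=n, flags=flags)


def lrt_pvalue(chi2: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    return float(stats.chi2.sf(chi2, df))


def cfi_from_chi2(chi2: float, df: int, chi2_b: float, df_b: int) -> float:
    """CFI = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)."""
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    return 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0


def rmsea_from_chi2(chi2: float, df: int, n: int) -> float:
    """RMSEA point estimate with the N - 1 denominator convention."""
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


def invariance_decision(p: float, delta_rmsea: float, delta_cfi: float) -> str:
    """Retain the constrained model when any lenient criterion holds.

    The rule is a disjunction: non-significant difference test (p > .05),
    RMSEA increase below .015, or CFI decrease below .010; ties go to the
    more parsimonious model.
    """
    retain = (p > 0.05) or (delta_rmsea < 0.015) or (delta_cfi < 0.010)
    return "retain_constrained" if retain else "retain_free"


@dataclass
class ComparisonResult:
    """Likelihood-ratio comparison of a constrained model to a freer one."""

    delta_chi2: float
    delta_df: int
    p: float
    delta_cfi: float
    delta_rmsea: float
    decision: str                      # 'retain_constrained' | 'retain_free'
    flags: list[str] = field(default_factory=list)


def chi_square_difference(constrained: FitResult, free: FitResult) -> ComparisonResult:
    """Nested-model chi-square difference test with index-change criteria.

    The constrained model is retained when any of the following holds:
    the difference test is non-significant (p > .05), the RMSEA increase is
    below .015, or the CFI decrease is below .010.  Ties favor the more
    parsimonious (constrained) model.
    """
    delta_df = constrained.df - free.df
    if delta_df < 0:
        raise ValueError("models are not nested (constrained has more free parameters)")
    if constrained.spec.n_moments != free.spec.n_moments:
        raise ValueError("models were not fitted to the same observed moments")
    flags: list[str] = []
    delta = 2.0 * (free.loglik - constrained.loglik)
    if delta < 0:
        if delta < -1e-6 * max(1.0, abs(free.loglik)):
            warnings.warn(f"negative delta chi-square {delta:.4g} clamped to 0", stacklevel=2)
        flags.append("delta_clamped")
        delta = 0.0
    # identical parameterizations: zero extra constraints, p = 1 by convention
    p = 1.0 if delta_df == 0 else lrt_pvalue(delta, delta_df)
    fi_c = compute_fit_indices(constrained)
    fi_f = compute_fit_indices(free)
    delta_cfi = fi_f.cfi - fi_c.cfi          # positive = fit worsens when constraining
    delta_rmsea = fi_c.rmsea - fi_f.rmsea    # positive = RMSEA rises when constraining
    return ComparisonResult(
        delta_chi2=float(delta), delta_df=int(delta_df), p=p,
        delta_cfi=float(delta_cfi), delta_rmsea=float(delta_rmsea),
        decision=invariance_decision(p, delta_rmsea, delta_cfi), flags=flags,
    )
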