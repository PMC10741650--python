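"""Univariable two-sample MR estimators and sensitivity analyses.

Implements the Wald ratio, fixed- and multiplicative-random-effects IVW,
MR-Egger regression with its pleiotropy intercept test, the weighted
median estimator with a seeded parametric bootstrap, Cochran's Q
heterogeneity test, leave-one-out analysis, an MR-PRESSO-style global and
per-instrument outlier test, and the Steiger directionality test.

All estimates are returned on the log-odds / linear scale with the odds
ratio and its 95% CI derived as exp(beta ± 1.96·se). P-values are
two-sided.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError
from .sumstats import InstrumentSet

__all__ = [
    "MREstimate",
    "HeterogeneityResult",
    "PleiotropyResult",
    "PressoResult",
    "SteigerResult",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
    "leave_one_out",
    "mr_presso",
    "steiger",
]

_Z95 = 1.96
_TINY_P = 5e-324  # keep p-values inside (0, 1]


def _two_sided_normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else _TINY_P
    return max(2.0 * stats.norm.sf(abs(beta) / se), _TINY_P)


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate from one method."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - _Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + _Z95 * self.se)


@dataclass(frozen=True)
class HeterogeneityResult:
    Q: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept: average directional pleiotropy."""

    intercept: float
    intercept_se: float
    pvalue: float


@dataclass(frozen=True)
class PressoResult:
    global_rss_p: float
    outlier_p: dict
    outliers: list
    corrected: MREstimate | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pvalue: float


def _require(instruments: InstrumentSet, minimum: int, what: str) -> None:
    if len(instruments) < minimum:
        raise InsufficientInstrumentsError(
            f"{what} requires at least {minimum} instruments, got {len(instruments)}"
        )


def _ratios_weights(instruments: InstrumentSet):
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    se_y = instruments.se_outcome
    if np.any(bx == 0):
        raise ValueError("zero exposure effect: Wald ratio undefined")
    return by / bx, (bx / se_y) ** 2


def wald_ratio(inst, second_order: bool = False) -> MREstimate:
    """Single-variant causal estimate beta_outcome / beta_exposure.

    The default SE is the first-order delta approximation
    se_outcome / |beta_exposure|; ``second_order`` adds the exposure
    uncertainty term.
    """
    if inst.beta_exposure == 0:
        raise ValueError("zero exposure effect: Wald ratio undefined")
    beta = inst.beta_outcome / inst.beta_exposure
    var = (inst.se_outcome / inst.beta_exposure) ** 2
    if second_order:
        var += inst.beta_outcome**2 * inst.se_exposure**2 / inst.beta_exposure**4
    se = math.sqrt(var)
    return MREstimate("wald_ratio", beta, se, _two_sided_normal_p(beta, se), 1)


def ivw(instruments: InstrumentSet, mode: str = "random") -> MREstimate:
    """Inverse-variance weighted estimate.

    Weighted mean of Wald ratios with weights (beta_exposure/se_outcome)²,
    equivalent to weighted through-origin regression of outcome effects on
    exposure effects with weights 1/se_outcome². ``mode="fixed"`` uses
    se = 1/sqrt(sum of weights); ``mode="random"`` multiplies the SE by
    sqrt(Q/(n−1)) when that exceeds 1 (multiplicative random effects).
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    _require(instruments, 2, "IVW")
    r, w = _ratios_weights(instruments)
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if mode == "random":
        q = float(np.sum(w * (r - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (len(r) - 1)))
    return MREstimate(f"ivw_{mode}", beta, se, _two_sided_normal_p(beta, se), len(r))


def egger(instruments: InstrumentSet):
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept, after orienting all exposure effects non-negative.

    Returns ``(MREstimate, PleiotropyResult)``. Coefficient SEs use the
    multiplicative random-effects rule (residual dispersion below 1 is not
    allowed to shrink them); p-values come from the t distribution with
    n − 2 degrees of freedom.
    """
    _require(instruments, 3, "MR-Egger")
    import statsmodels.api as sm

    sign = np.where(instruments.beta_exposure < 0, -1.0, 1.0)
    bx = instruments.beta_exposure * sign
    by = instruments.beta_outcome * sign
    se_y = instruments.se_outcome
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / se_y**2).fit()
    sigma = math.sqrt(res.scale)
    adj = 1.0 if sigma == 0 else max(1.0, sigma) / sigma
    inter, slope = res.params
    se_inter, se_slope = res.bse * adj
    df = len(instruments) - 2

    def t_p(b, s):
        if s == 0:
            return 1.0 if b == 0 else _TINY_P
        return max(2.0 * stats.t.sf(abs(b) / s, df), _TINY_P)

    est = MREstimate("egger", float(slope), float(se_slope), t_p(slope, se_slope), len(instruments))
    pleio = PleiotropyResult(float(inter), float(se_inter), t_p(inter, se_inter))
    return est, pleio


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cdf, r))


def weighted_median(
    instruments: InstrumentSet,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of Wald ratios (50% weighted breakdown point).

    The point estimate interpolates the inverse-variance-weighted
    empirical quantile function at 0.5. The SE is the standard deviation
    of the estimate over ``n_boot`` parametric-bootstrap draws of the
    exposure and outcome effects from their sampling distributions,
    seeded for reproducibility.
    """
    _require(instruments, 3, "weighted median")
    if n_boot < 100:
        warnings.warn("n_boot < 100: weighted-median SE will be unstable", UserWarning)
    r, w = _ratios_weights(instruments)
    beta = _weighted_median(r, w)

    rng = np.random.default_rng(seed)
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    se_x = instruments.se_exposure
    se_y = instruments.se_outcome
    draws = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(bx, se_x)
        by_b = rng.normal(by, se_y)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        draws[b] = _weighted_median(by_b / bx_b, (bx_b / se_y) ** 2)
    se = float(np.std(draws, ddof=1))
    return MREstimate("weighted_median", beta, se, _two_sided_normal_p(beta, se), len(r))


def cochran_q(instruments: InstrumentSet, beta_ref: float) -> HeterogeneityResult:
    """Cochran's Q for heterogeneity of Wald ratios around ``beta_ref``
    (chi-square with n − 1 degrees of freedom)."""
    _require(instruments, 2, "Cochran's Q")
    r, w = _ratios_weights(instruments)
    q = float(np.sum(w * (r - beta_ref) ** 2))
    df = len(r) - 1
    return HeterogeneityResult(q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(instruments: InstrumentSet, mode: str = "random"):
    """IVW estimates omitting one instrument at a time.

    Returns a list of ``(omitted_variant_id, MREstimate)`` pairs in
    instrument order.
    """
    _require(instruments, 3, "leave-one-out")
    results = []
    for inst in instruments:
        rest = instruments.drop([inst.variant_id])
        results.append((inst.variant_id, ivw(rest, mode=mode)))
    return results


def _loo_expected(bx, by, se_y):
    """Per-instrument leave-one-out IVW fit and expected outcome betas."""
    w = (bx / se_y) ** 2
    r = by / bx
    sw = np.sum(w, axis=-1, keepdims=True)
    swr = np.sum(w * r, axis=-1, keepdims=True)
    beta_loo = (swr - w * r) / (sw - w)
    return beta_loo * bx


def mr_presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_p_threshold: float = 0.05,
) -> PressoResult:
    """Simulation-based pleiotropy residual-sum-of-squares outlier test.

    Each instrument's squared, variance-standardised deviation from the
    leave-one-out IVW fit is compared against ``n_sim`` seeded parametric
    simulations under the no-pleiotropy model; the sum gives an empirical
    global p, and per-instrument empirical p-values (Bonferroni-adjusted
    over instruments) flag outliers. When outliers are found, an IVW
    estimate with them removed is reported as ``corrected``.
    """
    _require(instruments, 4, "MR-PRESSO")
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    se_x = instruments.se_exposure
    se_y = instruments.se_outcome
    if np.any(se_y == 0) or np.any(se_x == 0):
        raise ValueError("zero standard errors give a degenerate simulation")
    n = len(instruments)

    expected = np.asarray(_loo_expected(bx, by, se_y)).reshape(-1)
    obs = (by - expected) ** 2 / se_y**2
    rss_obs = float(np.sum(obs))

    rng = np.random.default_rng(seed)
    bx_s = rng.normal(bx, se_x, size=(n_sim, n))
    by_s = rng.normal(expected, se_y, size=(n_sim, n))
    bx_s[bx_s == 0] = np.finfo(float).tiny
    exp_s = _loo_expected(bx_s, by_s, se_y)
    obs_s = (by_s - exp_s) ** 2 / se_y**2
    rss_s = obs_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))
    p_raw = (1 + np.sum(obs_s >= obs, axis=0)) / (n_sim + 1)
    p_adj = np.minimum(1.0, p_raw * n)
    ids = instruments.variant_ids
    outlier_p = {vid: float(p) for vid, p in zip(ids, p_adj)}
    outliers = [vid for vid, p in outlier_p.items() if p < outlier_p_threshold]

    corrected = None
    if outliers:
        remaining = instruments.drop(outliers)
        if len(remaining) >= 2:
            inner = ivw(remaining, mode="random")
            corrected = MREstimate(
                "presso_corrected", inner.beta, inner.se, inner.pvalue, inner.n_snps
            )
    return PressoResult(global_p, outlier_p, outliers, corrected, n_sim, seed)


def steiger(instruments: InstrumentSet, n_exposure: int, n_outcome: int) -> SteigerResult:
    """Steiger directionality test.

    Variance explained per trait is summed over instruments using the
    t-statistic transform r²ⱼ = tⱼ²/(tⱼ² + n − 2); the causal direction
    is deemed correct when the instruments explain more variance in the
    exposure than in the outcome. The p-value uses the Fisher-z
    comparison of the two correlations (independent GWAS cohorts).
    """
    if n_exposure <= 3 or n_outcome <= 3:
        raise ValueError("sample sizes must exceed 3")
    _require(instruments, 1, "Steiger test")

    def r2(beta, se, n):
        t2 = (beta / se) ** 2
        return float(np.sum(t2 / (t2 + n - 2)))

    r2_exp = min(r2(instruments.beta_exposure, instruments.se_exposure, n_exposure), 1.0)
    r2_out = min(r2(instruments.beta_outcome, instruments.se_outcome, n_outcome), 1.0)
    r_exp = math.sqrt(r2_exp)
    r_out = math.sqrt(r2_out)
    z = (np.arctanh(min(r_exp, 1 - 1e-15)) - np.arctanh(min(r_out, 1 - 1e-15))) / math.sqrt(
        1.0 / (n_exposure - 3) + 1.0 / (n_outcome - 3)
    )
    p = max(2.0 * stats.norm.sf(abs(z)), _TINY_P)
    return SteigerResult(r2_exp, r2_out, r2_exp > r2_out, float(p))
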