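"""Multivariable MR and two-step mediation decomposition.

The two-step design estimates, for an exposure X, mediator M and outcome
Y:

* ``A`` — the total effect of X on M (univariable MR),
* ``B`` — the effect of M on Y adjusting for X (multivariable MR),
* ``C`` — the total effect of X on Y (univariable MR),
* ``C'`` — the direct effect of X on Y adjusting for M (the same
  multivariable MR).

The mediated (indirect) effect is the product A·B and the proportion
mediated is A·B / C; the difference-method proportion (C − C')/C is
reported alongside as a cross-check — the two agree exactly on noiseless
linear data. Cross-consortium covariances between the A, B and C
estimates are taken as zero (non-overlapping GWAS contrasts), the
standard assumption in two-step summary-data MR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CollinearityError, InsufficientInstrumentsError
from .estimators import _TINY_P, _Z95
from .sumstats import InstrumentSet

__all__ = [
    "MVMREstimate",
    "MediationDecomposition",
    "mvmr_ivw",
    "decompose_mediation",
    "proportion_ci",
]

#: Condition number of the weighted design above which a collinearity
#: warning is emitted (jointly modelled correlated exposures, e.g. the
#: two blood-pressure components, are hard to separate).
CONDITION_WARN = 30.0


@dataclass(frozen=True)
class MVMREstimate:
    """Joint (direct) effects of K exposures from multivariable IVW."""

    exposure_names: tuple
    betas: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    n_snps: int
    condition_number: float
    Q: float

    def __getitem__(self, name: str):
        """(beta, se, p) for one exposure by name."""
        i = self.exposure_names.index(name)
        return float(self.betas[i]), float(self.ses[i]), float(self.pvalues[i])


@dataclass
class MediationDecomposition:
    """A, B, C, C' and the derived mediation quantities.

    ``proportion`` is NaN (with ``proportion_defined`` False) when the
    total effect C is zero. ``ci_low``/``ci_high`` are populated by
    :func:`proportion_ci`.
    """

    A: float
    B: float
    C: float
    C_prime: float
    indirect: float
    proportion: float
    difference_proportion: float
    proportion_defined: bool
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str | None = None
    seed: int | None = None


def mvmr_ivw(instruments: InstrumentSet) -> MVMREstimate:
    """Multivariable IVW: weighted through-origin regression of outcome
    effects on the K exposure-effect columns, weights 1/se_outcome².

    The design columns are the exposure followed by the mediators in
    ``instruments.mediator_names`` order. Per-coefficient SEs come from
    the weighted normal equations with multiplicative overdispersion when
    residual Q/(n − K) exceeds 1. A rank-deficient design raises
    :class:`~mrmediate.errors.CollinearityError` naming the most
    correlated column pair; an ill-conditioned (but solvable) design
    emits a warning.
    """
    med = instruments.mediator_matrix
    if med is None:
        design = instruments.beta_exposure[:, None]
    else:
        design = np.column_stack([instruments.beta_exposure, med])
    names = (instruments.exposure_name, *instruments.mediator_names)
    n, k = design.shape
    if n <= k:
        raise InsufficientInstrumentsError(
            f"multivariable IVW with {k} exposures needs more than {k} instruments, got {n}"
        )
    y = instruments.beta_outcome
    w = 1.0 / instruments.se_outcome**2
    xw = design * np.sqrt(w)[:, None]
    cond = float(np.linalg.cond(xw))
    if not np.isfinite(cond) or cond > 1e10:
        if k < 2:
            raise CollinearityError("degenerate design: exposure effects are all zero")
        corr = np.corrcoef(design, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise CollinearityError(
            f"collinear exposures: '{names[i]}' and '{names[j]}' "
            f"(|r| = {abs(corr[i, j]):.4f})"
        )
    if cond > CONDITION_WARN:
        warnings.warn(
            f"ill-conditioned MVMR design (condition number {cond:.1f}); "
            "direct effects of correlated exposures are unstable",
            UserWarning,
        )
    xtwx = design.T @ (w[:, None] * design)
    betas = np.linalg.solve(xtwx, design.T @ (w * y))
    resid = y - design @ betas
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (n - k))
    ses = np.sqrt(scale * np.diag(np.linalg.inv(xtwx)))
    pvalues = np.maximum(2.0 * stats.norm.sf(np.abs(betas) / ses), _TINY_P)
    return MVMREstimate(names, betas, ses, pvalues, n, cond, q)


def decompose_mediation(C: float, A: float, B: float, C_prime: float) -> MediationDecomposition:
    """Two-step mediation decomposition.

    ``indirect = A·B``; ``proportion = A·B / C`` (product method) with the
    difference-method proportion ``(C − C')/C`` reported for
    cross-checking. A zero total effect flags the proportion as undefined
    rather than raising.
    """
    indirect = A * B
    if C == 0:
        return MediationDecomposition(
            A, B, C, C_prime, indirect, math.nan, math.nan, False
        )
    return MediationDecomposition(
        A, B, C, C_prime, indirect, indirect / C, (C - C_prime) / C, True
    )


def proportion_ci(
    decomp: MediationDecomposition,
    se_A: float,
    se_B: float,
    se_C: float,
    method: str = "bootstrap",
    n_boot: int = 10_000,
    seed: int = 0,
):
    """95% CI for the mediated proportion A·B / C.

    ``method="delta"`` propagates var(A·B) ≈ A²·se_B² + B²·se_A² and then
    the ratio variance treating A, B, C as uncorrelated.
    ``method="bootstrap"`` (default, preferred: the ratio is poorly
    normal) draws A, B and C from their normal sampling distributions
    ``n_boot`` times with a fixed seed and takes the percentile interval;
    a warning is raised when the total effect changes sign in more than
    1% of draws. Returns ``(ci_low, ci_high)`` and records the interval
    on ``decomp``.
    """
    if min(se_A, se_B, se_C) < 0:
        raise ValueError("standard errors must be non-negative")
    if not decomp.proportion_defined:
        raise ValueError("proportion undefined (total effect C = 0)")
    A, B, C = decomp.A, decomp.B, decomp.C
    prop = decomp.proportion
    if method == "delta":
        var_ind = A**2 * se_B**2 + B**2 * se_A**2
        var_prop = var_ind / C**2 + (A * B) ** 2 * se_C**2 / C**4
        half = _Z95 * math.sqrt(var_prop)
        lo, hi = prop - half, prop + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        a = rng.normal(A, se_A, n_boot)
        b = rng.normal(B, se_B, n_boot)
        c = rng.normal(C, se_C, n_boot)
        crossing = np.mean(np.sign(c) != np.sign(C))
        if crossing > 0.01:
            warnings.warn(
                f"total effect crosses zero in {100 * crossing:.1f}% of draws; "
                "the proportion CI is unstable",
                UserWarning,
            )
        c[c == 0] = np.finfo(float).tiny
        draws = a * b / c
        lo, hi = (float(q) for q in np.percentile(draws, [2.5, 97.5]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    decomp.ci_low, decomp.ci_high = float(lo), float(hi)
    decomp.ci_method = method
    decomp.seed = seed if method == "bootstrap" else None
    return float(lo), float(hi)
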