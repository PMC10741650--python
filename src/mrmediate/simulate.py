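"""Synthetic multi-trait GWAS summary statistics with known causal truth.

The generator emulates the summary-data landscape of a two-step
mediation MR study: a continuous exposure (a platelet index analogue), a
continuous mediator (a blood-pressure analogue) and a binary outcome (a
stroke analogue), measured in three non-overlapping GWAS cohorts.

Structural model on true per-allele effects, for variant j with exposure
effect γⱼ and mediator-specific effect δⱼ:

* exposure:  γⱼ (zero for mediator-specific instruments)
* mediator:  A·γⱼ + δⱼ
* outcome:   C'·γⱼ + B·(A·γⱼ + δⱼ) + pleiotropyⱼ

so that valid exposure instruments carry total effect
C = C' + A·B = ``causal_total`` and the mediated share is
``mediated_fraction``. Observed effects add sampling noise with
se = 1/sqrt(2·maf·(1−maf)·n); binary outcomes use the effective sample
size 4/(1/cases + 1/controls) and effects are generated directly on the
log-odds scale. Variants are simulated unlinked, matching the
post-clumping state the estimators assume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .sumstats import CANONICAL_COLUMNS, frame_from_associations  # noqa: F401  (re-export convenience)
import pandas as pd

__all__ = ["SimulationConfig", "SyntheticStudy", "simulate_study"]


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation truth and cohort layout.

    Defaults mirror the study conditions this package reproduces: 86
    exposure instruments (the plateletcrit instrument count), 95
    mediator-specific instruments (the blood-pressure instrument count),
    GWAS sample sizes 350,474 (exposure), 757,601 (mediator) and a
    40,585-case / 406,111-control binary outcome; total causal effect
    C = ln(1.113) ≈ 0.107 on the log-odds scale with 28% of it mediated,
    and an exposure→mediator effect A = ln(1.769) ≈ 0.570. Per-variant
    variance explained is drawn uniformly from ``exposure_r2_range``
    (instrument-scale effects, z well beyond genome-wide significance at
    these sample sizes).
    """

    n_variants: int = 86
    n_mediator_variants: int = 95
    maf_range: tuple = (0.05, 0.5)
    n_exposure: int = 350_474
    n_mediator: int = 757_601
    n_outcome: int = 446_696
    outcome_binary: bool = True
    case_fraction: float = 40_585 / 446_696
    causal_total: float = 0.107
    mediated_fraction: float = 0.28
    effect_on_mediator: float = 0.570
    exposure_r2_range: tuple = (2e-4, 8e-4)
    mediator_r2_range: tuple = (2e-4, 8e-4)
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mediated_fraction <= 1:
            raise ConfigurationError("mediated_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 1:
            raise ConfigurationError("maf_range must lie inside (0, 1)")
        for name in ("exposure_r2_range", "mediator_r2_range"):
            rlo, rhi = getattr(self, name)
            if not 0 < rlo <= rhi:
                raise ConfigurationError(f"{name} must be positive and ordered")
            if rhi >= 1:
                raise ConfigurationError(
                    f"{name} implies per-variant variance explained >= 1"
                )
        if self.exposure_r2_range[1] * self.n_variants >= 1:
            raise ConfigurationError("total exposure variance explained would exceed 1")
        if self.effect_on_mediator == 0 and self.mediated_fraction != 0:
            raise ConfigurationError(
                "mediated_fraction > 0 requires a non-zero exposure→mediator effect"
            )
        if self.pleiotropy_sd < 0 or not 0 <= self.invalid_fraction <= 1:
            raise ConfigurationError("invalid pleiotropy settings")
        for name in ("n_variants", "n_exposure", "n_mediator", "n_outcome"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.outcome_binary and not 0 < self.case_fraction < 1:
            raise ConfigurationError("case_fraction must lie in (0, 1)")

    @property
    def A(self) -> float:
        return self.effect_on_mediator

    @property
    def B(self) -> float:
        if self.effect_on_mediator == 0:
            return 0.0
        return self.causal_total * self.mediated_fraction / self.effect_on_mediator

    @property
    def C(self) -> float:
        return self.causal_total

    @property
    def C_prime(self) -> float:
        return self.causal_total * (1.0 - self.mediated_fraction)

    @property
    def n_outcome_effective(self) -> float:
        """Effective GWAS sample size (4/(1/cases + 1/controls) for a
        binary outcome, else the plain n)."""
        if not self.outcome_binary:
            return float(self.n_outcome)
        cases = self.case_fraction * self.n_outcome
        controls = self.n_outcome - cases
        return 4.0 / (1.0 / cases + 1.0 / controls)


@dataclass
class SyntheticStudy:
    """Simulator output: the truth and the emitted tables.

    ``truth`` records the structural parameters (A, B, C, C') and the
    per-variant true effects including pleiotropy; ``tables`` maps trait
    name ('exposure', 'mediator', 'outcome') to a canonical-header
    summary-statistics DataFrame. Tables regenerate bit-identically from
    (config, seed).
    """

    config: SimulationConfig
    truth: dict
    tables: dict

    def write(self, directory) -> None:
        """Write the three tables as TSV plus a truth.json sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(directory / f"{name}.tsv", sep="\t", index=False)
        sidecar = {
            "A": self.truth["A"],
            "B": self.truth["B"],
            "C": self.truth["C"],
            "C_prime": self.truth["C_prime"],
            "seed": self.config.seed,
        }
        (directory / "truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")


def _observe(true_beta: np.ndarray, maf: np.ndarray, n: float, rng) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta_hat = true_beta + rng.normal(0.0, se)
    pvals = np.maximum(2.0 * stats.norm.sf(np.abs(beta_hat / se)), 5e-324)
    return beta_hat, se, pvals


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one synthetic study from ``config`` (deterministic in the
    seed).

    Raises :class:`~mrmediate.errors.ConfigurationError` for parameter
    combinations implying per-variant variance explained ≥ 1 (checked at
    config construction).
    """
    rng = np.random.default_rng(config.seed)
    m_exp = config.n_variants
    m_med = config.n_mediator_variants
    m = m_exp + m_med

    maf = rng.uniform(*config.maf_range, size=m)
    var_allele = 2.0 * maf * (1.0 - maf)

    # instrument-scale true effects: per-variant variance explained drawn
    # uniformly, random sign (zero-mean overall)
    gamma = np.zeros(m)
    r2_exp = rng.uniform(*config.exposure_r2_range, size=m_exp)
    gamma[:m_exp] = rng.choice([-1.0, 1.0], size=m_exp) * np.sqrt(r2_exp / var_allele[:m_exp])
    delta = np.zeros(m)
    if m_med:
        r2_med = rng.uniform(*config.mediator_r2_range, size=m_med)
        delta[m_exp:] = rng.choice([-1.0, 1.0], size=m_med) * np.sqrt(
            r2_med / var_allele[m_exp:]
        )

    pleio = np.zeros(m)
    n_invalid = int(round(config.invalid_fraction * m_exp))
    if n_invalid and config.pleiotropy_sd > 0:
        idx = rng.choice(m_exp, size=n_invalid, replace=False)
        pleio[idx] = rng.normal(0.0, config.pleiotropy_sd, size=n_invalid)

    beta_med_true = config.A * gamma + delta
    beta_out_true = config.C_prime * gamma + config.B * beta_med_true + pleio

    variant_ids = np.array([f"rs{1_000_000 + j}" for j in range(m)])
    chromosomes = np.array([str(j % 22 + 1) for j in range(m)])
    positions = (np.arange(m) // 22 + 1) * 1_000_000 + (np.arange(m) % 22)
    alleles_ea = rng.choice(list("ACGT"), size=m)
    # pick a non-complementary other allele so harmonisation is exercised
    # without strand ambiguity
    _non_palindromic = {"A": ("C", "G"), "C": ("A", "T"), "G": ("A", "T"), "T": ("C", "G")}
    alleles_oa = np.array(
        [rng.choice(_non_palindromic[ea]) for ea in alleles_ea]
    )

    tables = {}
    for name, true_beta, n in (
        ("exposure", gamma, config.n_exposure),
        ("mediator", beta_med_true, config.n_mediator),
        ("outcome", beta_out_true, config.n_outcome_effective),
    ):
        beta_hat, se, pvals = _observe(true_beta, maf, n, rng)
        n_reported = config.n_outcome if name == "outcome" else int(n)
        tables[name] = pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chromosome": chromosomes,
                "base_pair_location": positions,
                "effect_allele": alleles_ea,
                "other_allele": alleles_oa,
                "effect_allele_frequency": maf,
                "beta": beta_hat,
                "standard_error": se,
                "p_value": pvals,
                "n": n_reported,
            }
        )

    truth = {
        "A": config.A,
        "B": config.B,
        "C": config.C,
        "C_prime": config.C_prime,
        "gamma": gamma,
        "delta": delta,
        "pleiotropy": pleio,
        "beta_mediator_true": beta_med_true,
        "beta_outcome_true": beta_out_true,
        "instrument_role": np.array(["exposure"] * m_exp + ["mediator"] * m_med),
    }
    return SyntheticStudy(config=config, truth=truth, tables=tables)
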