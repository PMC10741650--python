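"""Repeated-simulation experiments: calibration, recovery and detection.

These functions run the full summary-statistics path (simulate → QC →
harmonise → estimate) over many seeded replicates and are used both by
the test suite and by the reproduction script. Seeds for replicates are
spawned deterministically from a single master seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimators import cochran_q, ivw, mr_presso
from .mediation import mvmr_ivw
from .simulate import SimulationConfig, SyntheticStudy, simulate_study
from .sumstats import QCConfig, associations_from_frame, harmonize, select_instruments

__all__ = [
    "child_seeds",
    "univariable_instruments",
    "mvmr_instruments",
    "estimate_mediated_proportion",
    "ivw_coverage",
    "q_null_rejection_rate",
    "mediation_recovery",
    "presso_detection_rate",
]


def child_seeds(seed: int, n: int) -> list:
    """n reproducible sub-seeds (< 2**31) spawned from one master seed."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def univariable_instruments(
    study: SyntheticStudy,
    target: str = "outcome",
    qc: QCConfig | None = None,
):
    """QC the exposure table and harmonise it against one target trait."""
    exposure = associations_from_frame(study.tables["exposure"])
    kept, _ = select_instruments(exposure, qc or QCConfig())
    other = associations_from_frame(study.tables[target])
    return harmonize(kept, other, exposure_name="exposure", outcome_name=target)


def mvmr_instruments(study: SyntheticStudy, qc: QCConfig | None = None):
    """Union of exposure- and mediator-selected instruments, harmonised
    across exposure, mediator and outcome for multivariable IVW."""
    qc = qc or QCConfig()
    exposure = associations_from_frame(study.tables["exposure"])
    mediator = associations_from_frame(study.tables["mediator"])
    outcome = associations_from_frame(study.tables["outcome"])
    kept_exp, _ = select_instruments(exposure, qc)
    kept_med, _ = select_instruments(mediator, qc)
    ids = {a.variant_id for a in kept_exp} | {a.variant_id for a in kept_med}
    exp_subset = [a for a in exposure if a.variant_id in ids]
    return harmonize(
        exp_subset,
        outcome,
        mediators={"mediator": mediator},
        exposure_name="exposure",
        outcome_name="outcome",
    )


def estimate_mediated_proportion(study: SyntheticStudy) -> float:
    """Two-step estimate of the mediated proportion A·B / C on one study."""
    a_hat = ivw(univariable_instruments(study, "mediator")).beta
    c_hat = ivw(univariable_instruments(study, "outcome")).beta
    mv = mvmr_ivw(mvmr_instruments(study))
    b_hat, _, _ = mv["mediator"]
    return a_hat * b_hat / c_hat


def ivw_coverage(
    n_reps: int = 1000,
    seed: int = 0,
    config: SimulationConfig | None = None,
    mode: str = "random",
) -> float:
    """Fraction (%) of replicates whose IVW 95% CI covers the true total
    effect, under the no-pleiotropy model."""
    base = config or SimulationConfig(pleiotropy_sd=0.0, invalid_fraction=0.0)
    hits = 0
    for s in child_seeds(seed, n_reps):
        study = simulate_study(replace(base, seed=s))
        est = ivw(univariable_instruments(study, "outcome"), mode=mode)
        lo = est.beta - 1.96 * est.se
        hi = est.beta + 1.96 * est.se
        hits += lo <= base.causal_total <= hi
    return 100.0 * hits / n_reps


def q_null_rejection_rate(
    n_reps: int = 2000,
    seed: int = 0,
    n_instruments: int = 50,
    alpha: float = 0.05,
) -> float:
    """Cochran's Q rejection rate at ``alpha`` when no heterogeneity is
    simulated (Q evaluated at the fixed-effect IVW estimate)."""
    base = SimulationConfig(
        n_variants=n_instruments, n_mediator_variants=0, pleiotropy_sd=0.0
    )
    rejections = 0
    for s in child_seeds(seed, n_reps):
        study = simulate_study(replace(base, seed=s))
        inst = univariable_instruments(study, "outcome")
        het = cochran_q(inst, ivw(inst, mode="fixed").beta)
        rejections += het.pvalue < alpha
    return rejections / n_reps


def mediation_recovery(
    true_proportions=(0.0, 0.25, 0.5),
    n_reps: int = 200,
    seed: int = 0,
    config: SimulationConfig | None = None,
) -> dict:
    """Mean estimated mediated proportion per true value over seeded
    replicates; recovery is judged on the mean's distance to the truth."""
    base = config or SimulationConfig()
    means = {}
    for k, pi in enumerate(true_proportions):
        cfg = replace(base, mediated_fraction=pi)
        estimates = [
            estimate_mediated_proportion(simulate_study(replace(cfg, seed=s)))
            for s in child_seeds(seed + k, n_reps)
        ]
        means[pi] = float(np.mean(estimates))
    return means


def presso_detection_rate(
    n_reps: int = 100,
    seed: int = 0,
    n_clean: int = 20,
    displacement_sd: float = 10.0,
    n_sim: int = 1000,
) -> float:
    """Fraction (%) of replicates in which a single planted pleiotropic
    instrument (ratio displaced by ``displacement_sd`` combined SDs among
    ``n_clean`` clean instruments) is flagged as an outlier."""
    import dataclasses as _dc

    base = SimulationConfig(n_variants=n_clean, n_mediator_variants=0, pleiotropy_sd=0.0)
    detected = 0
    for s in child_seeds(seed, n_reps):
        study = simulate_study(replace(base, seed=s))
        inst = univariable_instruments(study, "outcome")
        target = inst.instruments[0]
        combined_sd = np.sqrt(
            target.se_outcome**2
            + (target.beta_outcome / target.beta_exposure) ** 2 * target.se_exposure**2
        )
        shifted = _dc.replace(
            target, beta_outcome=target.beta_outcome + displacement_sd * combined_sd
        )
        inst.instruments[0] = shifted
        res = mr_presso(inst, n_sim=n_sim, seed=s)
        detected += target.variant_id in res.outliers
    return 100.0 * detected / n_reps
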