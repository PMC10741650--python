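"""End-to-end orchestration: QC → univariable MR → sensitivity suite →
multivariable MR → mediation, from a single config, with a reproducible
report bundle.

The bundle contains, per exposure–outcome pair, the QC log, the estimate
table (IVW primary; MR-Egger and weighted median secondary), the
heterogeneity, pleiotropy, leave-one-out, MR-PRESSO and Steiger
diagnostics, the multivariable models, the mediation decompositions with
bootstrap CIs, and a JSON run manifest recording every seed and
threshold. Family-wise significance follows a Bonferroni rule
(``alpha_family / n_tests``, default 0.05/5 = 0.01); p-values between
the per-test threshold and 0.05 are labelled potentially significant.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from .estimators import (
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    mr_presso,
    steiger,
    weighted_median,
)
from .mediation import decompose_mediation, mvmr_ivw, proportion_ci
from .simulate import SimulationConfig, simulate_study
from .sumstats import QCConfig, associations_from_frame, harmonize, read_sumstats, select_instruments

logger = logging.getLogger("mrmediate")

__all__ = ["PipelineConfig", "run_pipeline", "format_or"]


def format_or(beta: float, se: float) -> str:
    """Render exp(beta) with its 95% CI to 3 decimals: "OR (low, high)"."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return (
        f"{math.exp(beta):.3f} "
        f"({math.exp(beta - 1.96 * se):.3f}, {math.exp(beta + 1.96 * se):.3f})"
    )


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs (simulation config or table
    paths), QC thresholds, estimator settings and the multiple-testing
    family."""

    simulation: SimulationConfig | None = None
    exposure_path: str | None = None
    mediator_paths: dict = field(default_factory=dict)
    outcome_paths: dict = field(default_factory=dict)
    exposure_name: str = "exposure"
    qc: QCConfig = field(default_factory=QCConfig)
    n_boot: int = 1000
    n_presso_sim: int = 1000
    seed: int = 0
    ivw_mode: str = "random"
    alpha_family: float = 0.05
    n_tests: int = 5

    @property
    def per_test_alpha(self) -> float:
        return self.alpha_family / self.n_tests

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "qc" in raw:
            qc = dict(raw["qc"])
            if "excluded_variants" in qc:
                qc["excluded_variants"] = frozenset(qc["excluded_variants"])
            kwargs["qc"] = QCConfig(**qc)
        inputs = raw.get("inputs", {})
        if "exposure" in inputs:
            kwargs["exposure_path"] = inputs["exposure"]["path"]
            kwargs["exposure_name"] = inputs["exposure"].get("name", "exposure")
        kwargs["mediator_paths"] = {
            m["name"]: m["path"] for m in inputs.get("mediators", [])
        }
        kwargs["outcome_paths"] = {
            o["name"]: o["path"] for o in inputs.get("outcomes", [])
        }
        for key in ("n_boot", "n_presso_sim", "seed", "ivw_mode", "alpha_family", "n_tests"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _significance(p: float, per_test_alpha: float) -> str:
    if p < per_test_alpha:
        return "significant"
    if p < 0.05:
        return "potentially significant"
    return "ns"


def _load_tables(config: PipelineConfig):
    """Return (exposure records, {mediator: records}, {outcome: records})."""
    if config.simulation is not None:
        study = simulate_study(config.simulation)
        return (
            associations_from_frame(study.tables["exposure"]),
            {"mediator": associations_from_frame(study.tables["mediator"])},
            {"outcome": associations_from_frame(study.tables["outcome"])},
        )
    if config.exposure_path is None or not config.outcome_paths:
        raise PipelineError("config must provide either a simulation or table paths")

    def load(path):
        result = read_sumstats(path)
        for problem in result.problems:
            logger.warning("%s: %s", path, problem)
        return result.records

    return (
        load(config.exposure_path),
        {name: load(path) for name, path in config.mediator_paths.items()},
        {name: load(path) for name, path in config.outcome_paths.items()},
    )


def _estimate_rows(inst, exposure, outcome, config):
    rows = []
    methods = [
        ivw(inst, mode="fixed"),
        ivw(inst, mode="random"),
        egger(inst)[0],
        weighted_median(inst, n_boot=config.n_boot, seed=config.seed),
    ]
    for est in methods:
        rows.append(
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": est.method,
                "n_snps": est.n_snps,
                "beta": est.beta,
                "se": est.se,
                "pvalue": est.pvalue,
                "or_ci": format_or(est.beta, est.se),
                "significance": _significance(est.pvalue, config.per_test_alpha),
            }
        )
    return rows


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run the whole workflow; return (and optionally write) the bundle.

    Stage failures abort with :class:`~mrmediate.errors.PipelineError`
    naming the stage and the offending trait pair.
    """
    stage = "load"
    pair = "-"
    try:
        exposure, mediators, outcomes = _load_tables(config)

        stage = "qc"
        kept, qc_log = select_instruments(exposure, config.qc)
        med_kept = {}
        for name, assocs in mediators.items():
            k, log_m = select_instruments(assocs, config.qc)
            med_kept[name] = k
            qc_log.extend((f"{name}:{vid}", reason) for vid, reason in log_m)

        est_rows, het_rows, pleio_rows, loo_rows, steiger_rows = [], [], [], [], []
        presso_out = {}
        total_effects = {}
        for out_name, out_assocs in outcomes.items():
            pair = f"{config.exposure_name}->{out_name}"
            stage = "harmonize"
            inst = harmonize(
                kept,
                out_assocs,
                palindromic_eaf_window=config.qc.palindromic_eaf_window,
                exposure_name=config.exposure_name,
                outcome_name=out_name,
            )
            qc_log.extend((f"{pair}:{vid}", reason) for vid, reason in inst.qc_log)

            stage = "steiger"
            n_exp = int(np.median([a.n for a in kept]))
            n_out = int(np.median([a.n for a in out_assocs]))
            direction = steiger(inst, n_exp, n_out)
            steiger_rows.append(
                {
                    "exposure": config.exposure_name,
                    "outcome": out_name,
                    "r2_exposure": direction.r2_exposure,
                    "r2_outcome": direction.r2_outcome,
                    "direction_correct": direction.direction_correct,
                    "pvalue": direction.pvalue,
                    "flag": "" if direction.direction_correct else "possible reverse causation",
                }
            )

            stage = "univariable-mr"
            est_rows.extend(_estimate_rows(inst, config.exposure_name, out_name, config))
            primary = ivw(inst, mode=config.ivw_mode)
            total_effects[out_name] = primary

            stage = "sensitivity"
            het_ivw = cochran_q(inst, ivw(inst, mode="fixed").beta)
            het_rows.append(
                {
                    "exposure": config.exposure_name,
                    "outcome": out_name,
                    "Q": het_ivw.Q,
                    "df": het_ivw.df,
                    "pvalue": het_ivw.pvalue,
                }
            )
            _, pleio = egger(inst)
            pleio_rows.append(
                {
                    "exposure": config.exposure_name,
                    "outcome": out_name,
                    "intercept": pleio.intercept,
                    "intercept_se": pleio.intercept_se,
                    "pvalue": pleio.pvalue,
                }
            )
            for vid, est in leave_one_out(inst, mode=config.ivw_mode):
                loo_rows.append(
                    {
                        "exposure": config.exposure_name,
                        "outcome": out_name,
                        "omitted": vid,
                        "beta": est.beta,
                        "se": est.se,
                        "pvalue": est.pvalue,
                    }
                )
            presso = mr_presso(inst, n_sim=config.n_presso_sim, seed=config.seed)
            presso_out[pair] = {
                "global_rss_p": presso.global_rss_p,
                "outliers": presso.outliers,
                "outlier_p": presso.outlier_p,
                "corrected_beta": presso.corrected.beta if presso.corrected else None,
                "corrected_se": presso.corrected.se if presso.corrected else None,
                "n_sim": presso.n_sim,
                "seed": presso.seed,
            }

        stage = "exposure-to-mediator"
        a_estimates = {}
        for med_name, med_assocs in mediators.items():
            pair = f"{config.exposure_name}->{med_name}"
            inst_a = harmonize(
                kept,
                med_assocs,
                palindromic_eaf_window=config.qc.palindromic_eaf_window,
                exposure_name=config.exposure_name,
                outcome_name=med_name,
            )
            a_estimates[med_name] = ivw(inst_a, mode=config.ivw_mode)
            est_rows.extend(_estimate_rows(inst_a, config.exposure_name, med_name, config))

        stage = "mvmr"
        mvmr_rows = []
        mediation_rows = []
        med_names = list(mediators)
        models = [[m] for m in med_names]
        if len(med_names) > 1:
            models.append(med_names)
        for out_name, out_assocs in outcomes.items():
            for model in models:
                pair = f"{'+'.join(model)}+{config.exposure_name}->{out_name}"
                ids = {a.variant_id for a in kept}
                for m in model:
                    ids |= {a.variant_id for a in med_kept[m]}
                exp_subset = [a for a in exposure if a.variant_id in ids]
                inst_mv = harmonize(
                    exp_subset,
                    out_assocs,
                    mediators={m: mediators[m] for m in model},
                    palindromic_eaf_window=config.qc.palindromic_eaf_window,
                    exposure_name=config.exposure_name,
                    outcome_name=out_name,
                )
                mv = mvmr_ivw(inst_mv)
                for name in mv.exposure_names:
                    b, s, p = mv[name]
                    mvmr_rows.append(
                        {
                            "model": pair,
                            "outcome": out_name,
                            "exposure": name,
                            "n_snps": mv.n_snps,
                            "beta": b,
                            "se": s,
                            "pvalue": p,
                            "or_ci": format_or(b, s),
                            "condition_number": mv.condition_number,
                        }
                    )

                stage = "mediation"
                if len(model) == 1:
                    med_name = model[0]
                    a_est = a_estimates[med_name]
                    c_est = total_effects[out_name]
                    b_val, b_se, _ = mv[med_name]
                    cp_val, _, _ = mv[config.exposure_name]
                    decomp = decompose_mediation(c_est.beta, a_est.beta, b_val, cp_val)
                    if decomp.proportion_defined:
                        proportion_ci(
                            decomp,
                            a_est.se,
                            b_se,
                            c_est.se,
                            method="bootstrap",
                            n_boot=config.n_boot,
                            seed=config.seed,
                        )
                        delta_lo, delta_hi = proportion_ci(
                            dataclasses.replace(decomp),
                            a_est.se,
                            b_se,
                            c_est.se,
                            method="delta",
                        )
                    else:
                        delta_lo = delta_hi = math.nan
                    mediation_rows.append(
                        {
                            "exposure": config.exposure_name,
                            "mediator": med_name,
                            "outcome": out_name,
                            "A": decomp.A,
                            "B": decomp.B,
                            "C": decomp.C,
                            "C_prime": decomp.C_prime,
                            "indirect": decomp.indirect,
                            "proportion": decomp.proportion,
                            "proportion_pct": 100.0 * decomp.proportion,
                            "ci_low": decomp.ci_low,
                            "ci_high": decomp.ci_high,
                            "ci_method": decomp.ci_method,
                            "delta_ci_low": delta_lo,
                            "delta_ci_high": delta_hi,
                            "difference_proportion": decomp.difference_proportion,
                        }
                    )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed for {pair}: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_boot": config.n_boot,
        "n_presso_sim": config.n_presso_sim,
        "ivw_mode": config.ivw_mode,
        "alpha_family": config.alpha_family,
        "n_tests": config.n_tests,
        "per_test_alpha": config.per_test_alpha,
        "qc": {
            "p_threshold": config.qc.p_threshold,
            "ld_r2_threshold": config.qc.ld_r2_threshold,
            "f_threshold": config.qc.f_threshold,
            "excluded_variants": sorted(config.qc.excluded_variants),
            "palindromic_eaf_window": config.qc.palindromic_eaf_window,
        },
        "simulation": dataclasses.asdict(config.simulation) if config.simulation else None,
    }

    bundle = {
        "qc_log": qc_log,
        "estimates": pd.DataFrame(est_rows),
        "heterogeneity": pd.DataFrame(het_rows),
        "pleiotropy": pd.DataFrame(pleio_rows),
        "leave_one_out": pd.DataFrame(loo_rows),
        "presso": presso_out,
        "steiger": pd.DataFrame(steiger_rows),
        "mvmr": pd.DataFrame(mvmr_rows),
        "mediation": pd.DataFrame(mediation_rows),
        "manifest": manifest,
    }
    if outdir is not None:
        _write_bundle(bundle, outdir)
    return bundle


def _write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("estimates", "heterogeneity", "pleiotropy", "leave_one_out", "steiger", "mvmr", "mediation"):
        bundle[name].to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "qc_log.txt", "w") as fh:
        for vid, reason in bundle["qc_log"]:
            fh.write(f"{vid}\t{reason}\n")
    (outdir / "presso.json").write_text(json.dumps(bundle["presso"], indent=2) + "\n")
    (outdir / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2) + "\n")
    logger.info("report bundle written to %s", outdir)
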