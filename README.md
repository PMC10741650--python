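# mrmediate

Two-sample Mendelian randomization (MR) with multivariable MR and
two-step mediation analysis, for GWAS summary statistics.

`mrmediate` is built for epidemiologists asking whether a heritable
exposure (the motivating case: plateletcrit, the platelet volume
fraction of blood) causally raises the risk of a disease outcome (here:
ischemic stroke), and how much of that effect flows through a measured
mediator (here: systolic and diastolic blood pressure). It provides the
whole summary-data workflow: instrument QC and allele harmonisation, the
univariable estimator suite with sensitivity analyses, multivariable MR,
the mediation decomposition with bootstrap confidence intervals, and a
synthetic GWAS generator with known causal truth so every stage is
testable without access to the original consortium data.

## The model

For genetic variant *j*, let β̂ˣⱼ and β̂ʸⱼ be its estimated per-allele
effects on exposure *X* and outcome *Y* in two non-overlapping GWAS. If
the variant is a valid instrument, the Wald ratio β̂ʸⱼ/β̂ˣⱼ estimates
the causal effect of *X* on *Y*. The primary estimator is the
inverse-variance weighted (IVW) mean of the ratios,

    β_IVW = Σⱼ wⱼ (β̂ʸⱼ/β̂ˣⱼ) / Σⱼ wⱼ,   wⱼ = (β̂ˣⱼ/seʸⱼ)²,

equivalent to weighted through-origin regression of β̂ʸ on β̂ˣ.
Secondary estimators guard against pleiotropy: MR-Egger (free intercept
= average directional pleiotropy), the weighted median (consistent while
valid instruments hold > 50% of the weight), and an MR-PRESSO-style
simulation test that flags and removes outlier instruments. Cochran's Q,
leave-one-out, and the Steiger directionality test complete the
sensitivity suite.

Mediation uses the two-step decomposition: with

* **A** — total effect of *X* on mediator *M* (univariable MR),
* **B** — effect of *M* on *Y* adjusted for *X* (multivariable IVW),
* **C** — total effect of *X* on *Y*, and
* **C′** — direct effect of *X* on *Y* adjusted for *M*,

the indirect (mediated) effect is **A·B** and the proportion mediated is
**A·B / C**, with a seeded parametric-bootstrap CI (delta method as a
cross-check). The difference-method proportion (C − C′)/C is reported
alongside; the two agree exactly on noiseless linear data.

## Worked example

Simulate a study at consortium scale (86 exposure instruments at
n = 350,474; 95 mediator instruments at n = 757,601; a binary outcome
with 40,585 cases / 406,111 controls; true total effect
C = 0.107 ≈ ln 1.113 with 28% mediated) and run the full pipeline:

```python
from mrmediate import SimulationConfig, PipelineConfig, run_pipeline

config = PipelineConfig(simulation=SimulationConfig(seed=7), seed=7)
bundle = run_pipeline(config)
print(bundle["estimates"].query("outcome == 'outcome'"))
print(bundle["mediation"])
```

prints (columns abridged):

```
         method  n_snps     beta       se       pvalue                or_ci
      ivw_fixed      86 0.117340 0.012905 9.642125e-20 1.125 (1.096, 1.153)
     ivw_random      86 0.117340 0.012990 1.669417e-19 1.125 (1.096, 1.154)
          egger      86 0.133129 0.047318 6.101734e-03 1.142 (1.041, 1.253)
weighted_median      86 0.107023 0.018909 1.513734e-08 1.113 (1.072, 1.155)

     A      B      C  C_prime  indirect  proportion_pct  ci_low  ci_high
0.5705 0.0575 0.1173   0.0815    0.0328         27.9629  0.1577   0.4276
```

The IVW odds ratio 1.125 (1.096, 1.153) covers the simulated truth
exp(0.107) = 1.113; all four estimators agree; and the estimated
mediated proportion 27.96% [95% CI 15.8–42.8%] recovers the simulated
28%. Cochran's Q on this run is 86.13 (df 85, p = 0.445 — no
heterogeneity, as simulated), and the Steiger test confirms the forward
causal direction.

The same workflow is available from the shell:

```sh
mrmediate simulate --seed 7 --out sim/
mrmediate run-all --config config.yaml --out report/
```

with subcommands `qc`, `mr`, `mvmr` and `mediate` for the individual
stages.

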