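# netmr — network Mendelian randomization from GWAS summary statistics

`netmr` estimates how much of an exposure's causal effect on a disease
outcome flows through intermediate traits, using nothing but published GWAS
summary statistics. It implements the network (mediation) Mendelian
randomization design: univariable two-sample MR gives the **total** effect of
the exposure on the outcome, multivariable MR (MVMR) gives the **direct**
effect conditional on one or more mediators, and the difference method on the
log-odds scale gives the **indirect** effect and the **proportion mediated**

```
PM = beta_indirect / beta_total = 1 − ln(OR_direct) / ln(OR_total).
```

It is written for epidemiologists and statistical geneticists who want a
reproducible, scriptable alternative to stitching the pieces together by
hand: instrument selection (p < 5×10⁻⁸, greedy clumping), allele
harmonization, the estimator battery — inverse-variance-weighted (IVW,
fixed/multiplicative-random with the Q-driven auto switch), MR-Egger,
maximum likelihood, MR-RAPS — plus the full sensitivity kit: Cochran's Q,
Egger intercept, MR-PRESSO global/outlier/distortion tests, Steiger
directionality, leave-one-out, instrument F statistics, and analytic power
for binary outcomes.

Because real GWAS downloads are large and access-controlled, the package
ships a synthetic summary-statistics generator (`netmr.simgwas`) with a known
exposure → {mediators} → outcome causal graph. Its default scenario encodes
an education → {neuroticism, BMI, smoking, household income} → major
depressive disorder network at real GWAS sample sizes, so every estimator can
be validated against known ground truth.

## Worked example

```python
import warnings
from netmr import NetworkConfig, NetworkScenario, run_network, simulate_network_sumstats

scenario = NetworkScenario(seed=1)          # education -> 4 mediators -> MDD
tables, truth = simulate_network_sumstats(scenario)

config = NetworkConfig(
    sumstats={name: f"{name}.tsv" for name in scenario.trait_names},
    exposure="education", outcome="mdd",
    mediators=list(scenario.mediator_names),
    seed=99, outcome_case_fraction=scenario.case_fraction,
)
report = run_network(config, tables)

print(report.edges[("education", "mdd")].headline.summary())
for m in report.mediation:
    print(m.summary())
```

prints (exactly, given these seeds):

```
IVW_FE (fixed), 256 SNPs
  beta = -0.3674 (SE 0.0152), p = 1.58e-128
  OR = 0.692 (95% CI 0.672-0.713)
  Cochran Q = 243.78 on 255 df, p = 0.683

education -> mdd via neuroticism: total = -0.3674 (OR 0.692), direct = -0.1627 (OR 0.850), indirect = -0.2047, PM = 55.72% (95% CI 0.458-0.656)
education -> mdd via bmi: total = -0.3674 (OR 0.692), direct = -0.3042 (OR 0.738), indirect = -0.0633, PM = 17.22% (95% CI 0.063-0.281)
education -> mdd via smoking: total = -0.3674 (OR 0.692), direct = -0.2533 (OR 0.776), indirect = -0.1141, PM = 31.06% (95% CI 0.211-0.410)
education -> mdd via income: total = -0.3674 (OR 0.692), direct = -0.0728 (OR 0.930), indirect = -0.2947, PM = 80.20% (95% CI 0.655-0.949)
education -> mdd via neuroticism+bmi+smoking+income: total = -0.3674 (OR 0.692), direct = +0.2904 (OR 1.337), indirect = -0.6578, PM = 179.03% (95% CI 1.616-1.965)
```

Reading the output: one standard deviation more schooling lowers MDD odds by
~31% (OR 0.692); roughly half of that effect is carried by neuroticism,
about a sixth by BMI, a third by smoking, and four-fifths by household
income. The simulated ground truth for these proportions is
{52.92, 15.54, 31.86, 81.30}% — each estimate lands within a few points.
The single-mediator proportions may legitimately sum to more than 100%
(mediators share pathways); the joint row reports the decomposition with all
four mediators adjusted simultaneously and is flagged as inconsistent
mediation (PM outside [0, 1]) rather than clipped.

The same run is available from the shell:

```bash
netmr simulate --seed 1 --out-dir sim/
netmr univariable --exposure sim/education.sumstats.tsv \
    --outcome sim/mdd.sumstats.tsv --seed 2 --case-fraction 0.346 --out-dir uv/
netmr network --config network.yaml --out-dir results/
```

`netmr network` writes a report bundle: `univariable.tsv` (one row per
estimator per edge with OR, CI, Q, Egger-intercept, Steiger and power
columns), `mediation.tsv` (direct-effect ORs and PM per adjustment set),
per-edge leave-one-out and MR-PRESSO outlier tables, drop logs, and a
`manifest.json` with the config hash and seed.

## Layout

| module | contents |
| --- | --- |
| `netmr.sumstats` | TSV reading/validation, instrument selection, clumping, harmonization |
| `netmr.uvmr` | `IVW`, `MREgger`, `MaximumLikelihood`, `RAPS` models; Q, Steiger, LOO, power |
| `netmr.presso` | `MRPresso` global / outlier / distortion tests |
| `netmr.mediation` | `MVMR`, `mediation_decompose`, `NetworkMR` orchestration |
| `netmr.simgwas` | `NetworkScenario` ground-truth generator |
| `netmr.cli` | `netmr` command with simulate/harmonize/univariable/mvmr/network |

See `docs/methods.md` for the model, its assumptions, and the numerical
choices.
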