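# otrisk

Reverse dosimetry and cancer-risk assessment for **ortho-toluidine**
(OT, 2-aminotoluene) from human-biomonitoring data.

OT is an aromatic amine used in dye, rubber and epoxy chemistry, a
genotoxic bladder carcinogen, and — because dermal uptake matters — a
substance whose exposure is best monitored in urine rather than air.
Published studies, however, report only urinary *summary statistics*
(mean, SD, median, P95, max of total OT after hydrolysis of conjugates),
while risk characterisation needs the *external daily intake*. This
package, aimed at occupational/environmental risk assessors and
toxicokinetic modellers, closes that gap along the complete chain:

1. **Urinary mass balance** (first tier): at steady state
   `Css = D·BW·FUE / V24`, with fractional urinary excretion
   FUE = 0.75, urine volume V24 = 1.5 L/d and BW = 70 kg, inverted in
   closed form (`D = Css·V24 / (FUE·BW)`).
2. **PBPK exposure reconstruction** (second tier): a flow-limited
   whole-body model of OT and its metabolite OH-o-toluidine (11 tissue
   compartments + blood, hepatic Michaelis–Menten metabolism with
   Km = 27.2 µmol/L and Vmax = 2835.3 µmol/h, renal clearance of the
   metabolite at 0.17 L/min), inverted by Metropolis–Hastings MCMC:
   lognormal prior on intake, lognormal observation error (GSD 1.5), and
   30%-CV lognormal nuisance variability on body weight and metabolic
   capacity. Because post-shift spot samples are peaks rather than
   steady-state levels, this tier yields systematically *lower* intakes
   than tier 1 — by roughly 20–30% — for worker studies.
3. **Linear risk extrapolation**: lifetime excess bladder-tumour risk
   `risk(d) = 0.1 · d / POD`, with points of departure derived from a
   rat benchmark dose BMD10 = 42.2 mg/kg bw/d (occupational:
   210 mg/m³ ≙ 30 mg/kg bw per working day after duration adjustment and
   rat→human allometric scaling by 4; general population:
   10.6 mg/kg bw/d).

Seven published biomonitoring studies (4 occupational, 3 general
population, smoking strata kept separate) ship as a typed, validated
registry. A synthetic-cohort module generates biomonitoring datasets with
known ground-truth intakes so the whole inversion chain is testable end
to end. See `docs/methods.md` for the model details and assumptions.

## Worked example

The highest-exposure occupational study reports a mean post-shift
urinary level of 523 µg/L. Reconstructing the external intake:

```bash
otrisk reconstruct --study-id labat --statistic mean --seed 1
```

```
Exposure reconstruction (PBPK inversion, Metropolis-Hastings)
==============================================================
observed urinary statistic : 523 ug/L
mass-balance point estimate: 0.0149429 mg/kg bw/d
prior median / GSD         : 0.0149429 / 3
chains x retained draws    : 4 x 2500
acceptance rate            : 0.312
--------------------------------------------------------------
posterior median intake    : 0.0123852 mg/kg bw/d
posterior mean intake      : 0.0133646 mg/kg bw/d
95% credible interval      : [0.00572619, 0.0266255]
--------------------------------------------------------------
param        R-hat    ESS
intake        1.001     1035
bw_multiplier  1.005      726
met_multiplier  1.010      706
```

The closed-form mass balance turns 523 µg/L into 14.94 µg/kg bw/d; the
PBPK inversion of the same observation gives a posterior median of
12.4 µg/kg bw/d, lower because the model attributes part of the
post-shift peak to the 8-h shift dynamics rather than to steady-state
intake. On the occupational risk scale both correspond to a lifetime
excess bladder-cancer risk of a few times 10⁻⁵
(`occupational_risk(0.0124) ≈ 4.1e-05`, rendered `41:10^6`).

The same from Python, statsmodels-style:

```python
from otrisk import ExposureReconstruction, ReconstructionConfig, get_study

model = ExposureReconstruction.from_study(get_study("labat"), "mean",
                                          config=ReconstructionConfig(seed=1))
results = model.fit()
print(results.summary())          # table above
results.median                    # 0.01238... mg/kg bw/d
results.credible_interval()       # (0.0057, 0.0266)
```

Other entry points: `otrisk massbalance` (closed-form conversions, e.g.
the 0.5 mg/m³ occupational limit ↔ 2.5 mg/L urinary equivalent),
`otrisk simulate` (PBPK time courses), `otrisk risk-table --population
worker|general` (the regenerated risk scales, e.g. the worker 1:10,000
row reads 0.21 mg/m³ / 0.03 mg/kg bw/d / 1 mg/L), `otrisk synth`
(synthetic cohorts) and `otrisk reproduce-tables` (all result tables,
with exact verification of every closed-form cell).

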