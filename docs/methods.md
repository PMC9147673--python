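# Methods

This note documents the models implemented in `otrisk`, the assumptions
and parameter choices behind them, and what the test suite does and does
not demonstrate.

## Problem

Urinary biomonitoring of ortho-toluidine (OT, 2-aminotoluene) reports the
concentration of total OT — free plus conjugated, measured after
hydrolysis — in post-shift spot samples of workers (µg/L) or 24-h
collections of the general population (ng/24 h). Risk assessment needs
the *external* daily intake behind those levels. The package solves this
inversion twice, at two levels of sophistication, and converts the
resulting intakes to lifetime excess bladder-cancer risks by linear
extrapolation from a rat benchmark dose.

## Tier 1: urinary mass balance

At steady state, daily excreted biomarker mass equals a fixed fraction of
daily absorbed dose:

```
Css = D · BW · FUE / V24          D = Css · V24 / (FUE · BW)
```

with FUE = 0.75 (24-h urinary recovery of total OT in subcutaneously
dosed rats), V24 = 1.5 L, BW = 70 kg, and 10 m³ of air inhaled over an
8-h working day for air-to-intake conversion. A 24-h collection is
already a daily mass, so only FUE·BW enters that variant. All conversions
are linear, exact inverses of each other, and implemented in canonical
units (mg, kg, L, m³, day) with µg/L and ng/24 h handled at the
interface. The published expression for the background-guidance-value
conversion is typeset ambiguously; the grouping (0.2 × 1.5)/(0.75 × 70)
is the one that reproduces its stated result (5.7 ng/kg bw/d) and is the
one implemented.

The key assumption — and the known weakness — is that the measured level
*is* a steady-state level. A post-shift sample from a rapidly eliminated
chemical (OT plasma half-life ≈ 4 h) is a peak, not a steady state, so
tier 1 overestimates intake for workers. Quantifying that overestimate is
exactly what tier 2 adds.

## Tier 2: PBPK model and Bayesian inversion

### Structure

A flow-limited whole-body model with eleven tissue compartments (GI,
liver, kidney, fat, bone, brain, gonads, heart, muscle, skin, lung) plus
a lumped blood pool, duplicated for parent OT and its metabolite
OH-o-toluidine. Tissues equilibrate with venous outflow through
tissue:blood partition coefficients; the GI compartment drains through
the liver (portal circulation); inhaled mass enters the blood pool
directly (complete absorption, equal to oral); oral doses pass through a
gut depot with first-order absorption (rate 1/h, fraction 1) into the GI
tissue. The liver converts parent to metabolite with Michaelis–Menten
kinetics (Km = 27.2 µmol/L, Vmax = 2835.3 µmol/h) acting on the free
venous concentration (free fraction = 1 − 0.035 − 0.005). The kidney
clears the metabolite at 0.17 L/min; the parent's renal clearance is
zero. All compound parameters are the published QSAR-derived set and are
echoed verbatim by the default `PbpkParameterSet`.

Internally the state vector is in micromoles, which makes the mass
ledger (absorbed = in-body + excreted + other pathways) exact up to
solver error; the simulation asserts conservation to a relative 1e-6.

### Two conventions that required a decision

* **Renal clearance acts on total blood concentration.** An empirical
  kidney clearance in L/min refers to the volume of measured (total)
  blood cleared per unit time. Applying it to the free concentration
  (free fraction 0.05 for the metabolite) would stretch the metabolite's
  half-life to ~50 h, irreconcilable with the ~4 h plasma half-life
  reported for OT in humans and with the existence of a pronounced
  post-shift peak. With the total-concentration convention the
  metabolite's effective half-life is ≈ 2.5 h and the parent's ≈ 3.4 h,
  consistent with that observation. Metabolism, by contrast, is a
  mechanistic enzyme rate and acts on the free concentration.
* **Biomarker calibration.** The measured analyte (total OT after
  hydrolysis) is not literally the ring-hydroxylated metabolite the model
  tracks, but all parent is routed through that pathway, so at steady
  state cumulative renal output equals absorbed dose mole-for-mole. The
  urinary biomarker is therefore the renally excreted pathway output in
  parent-equivalents multiplied by a single named constant
  `biomarker_recovery` = FUE = 0.75, which makes the PBPK tier agree with
  the mass-balance tier at steady state by construction. A simulation
  test confirms the realised 24-h steady-state recovery is 0.75 ± 1%.

### Reference physiology

The anatomy/physiology is not part of the published parameter set, so a
standard ICRP-style reference adult is fixed in `physiology.py`
(70 kg, cardiac output 390 L/h, perfused tissue volumes summing to
61 L including 5.3 L blood, flow fractions summing to exactly 1 with
muscle as the balancing term, ventilation 1.25 m³/h at light work, urine
flow 1.5 L/24 h). Body-size variants scale volumes linearly with weight
and perfusion with weight^0.75; ventilation and urine flow stay fixed
because the 10 m³/working day and 1.5 L/day values are treated as
population constants throughout the framework. Every number lives in one
versioned constants file because each of them changes model output.

### Exposure scenarios and urine sampling

Workers: inhalation at a constant air concentration over an 8-h shift
(06:00–14:00), 5 days per week, simulated over a working week; urine
voids at shift start, shift end, +4 h and +8 h, repeating daily. The
"post-shift" value is the void at shift end on the last exposed day —
i.e. bladder content accumulated over the shift divided by the urine
volume produced in that interval. General population: continuous oral
intake with a 24-h pooled collection, simulated to steady state (4 days
covers it; the slowest relevant time constant is a few hours).

Because excretion lags exposure through the two-stage
(parent → metabolite) cascade, the excretion peak falls shortly *after*
shift end; the post-shift void exceeds the daily average by ~20% at
these kinetics, and the first evening void is higher still.

### The inversion

The reconstruction treats a reported summary statistic as a single
lognormal observation of the forward-model prediction (geometric SD 1.5
by default) — only summary data exist, so nothing finer is identifiable.
Parameters: intake D (lognormal prior, median at the tier-1 point
estimate, GSD 3, weakly informative; GSD ∈ {2, 5} available as a
sensitivity diagnostic) and two nuisance multipliers — body weight, and a
joint metabolic multiplier on Vmax — lognormal with median 1 and CV 0.30
each, the stated carriers of inter-individual variability. Sampling is
random-walk Metropolis–Hastings on log-parameters (the exp-transform
Jacobian is included in the target; omitting it biases every lognormal
summary low). Defaults: 4 chains, 2000 burn-in draws per chain, 10,000
pooled retained draws. Convergence is monitored by split-chain
Gelman–Rubin (warn above 1.1) and autocorrelation-based effective sample
size. A differential-evolution ensemble sampler is available behind the
same contract but is not the default.

Over the entire biomonitoring range the forward model is linear in dose
(Michaelis–Menten linearises far below Km; deviation < 0.1% is verified
up to 50 mg/kg bw/d-equivalents), so the default configuration caches
the response per unit intake on a 5×5 grid of the two log-multipliers
(span ±3.5 prior SDs) and interpolates log-linearly; each posterior
evaluation then costs microseconds instead of an ODE solve. The cache is
licensed at fit time by an explicit linearity check at 1%.

### Numerical choices

LSODA with rtol 1e-8, atol 1e-10, integrated piecewise between exposure
on/off boundaries so discontinuities never cross a solver step; output
grid 0.1 h by default (0.5 h inside the cached map, where only void-time
cumulative values matter — void times are inserted into the grid
exactly). States are clipped at zero to remove solver noise at the atol
level. Proposal scale 0.55 on log-intake (≈ 28% acceptance); chain seeds
are spawned from one `SeedSequence`, making every reconstruction
bit-reproducible given its seed.

## Risk tier

Linear extrapolation through the origin from risk 0.1 at the point of
departure. Occupational POD: BMD10 = 42.2 mg/kg bw/d × 70 kg ÷ 10 m³ ×
duration adjustment ÷ allometric factor 4 = 210 mg/m³ (≙ 30 mg/kg bw per
working day). The published derivation states the schedule assumptions
but not the arithmetic of the factor ≈ 2.84 needed to reach its printed
rat-equivalent air level of 840 mg/m³; it is implemented as an explicit,
configurable `duration_adjustment` with default
(7·52)/(5·48) × (75/40) = 2.844 — continuous-versus-working schedule
times lifetime-versus-working-years — which reproduces 840 to three
significant figures. This decomposition is a reconstruction, not a quoted
derivation. General-population POD: 42.2/4 = 10.6 mg/kg bw/d, no
duration adjustment (the underlying rat study was continuous feeding).

Report tables apply the published rounding conventions (half-up at the
printed decimals; the occupational urinary column is printed at one
significant figure), with exact arithmetic always available. The
published general-population reverse-dosimetry table carries a risk
column about tenfold lower than its own dose column times the published
general-population slope; the package computes risks from the slope and
flags the inconsistency in the report notes rather than matching it.

## Synthetic cohorts and what the tests show

`SyntheticCohortSpec` draws per-subject intakes (lognormal, default
median 15 µg/kg bw/d with GSD 1.8 — the scale and spread of the
highest-exposure worker study), body-weight and metabolic multipliers
(CV 0.30, mapped to log-scale SD via σ = √ln(1+CV²)), a forward model,
and multiplicative assay noise (default GSD 1.2). The fast generator is
the closed-form mass balance and therefore emulates *steady-state*
urinary levels; its observations are inverted with the matching
steady-state sampling plan. The PBPK generator simulates each subject
through the shift scenario and produces genuine post-shift samples. The
recovery harness compares the posterior to the realised cohort value of
the inverted statistic (mean intake when inverting the concentration
mean), because that — not the design median — is what a summary-level
inversion estimates.

Passing recovery tests (|bias| < 20%, ≥ 85% CI coverage over 50 seeded
replicates) therefore show that the inversion machinery is calibrated
when the error model is no narrower than the actual noise and when the
sampling plan matches how the data arose. They do not validate the PBPK
parameters against human kinetic data (none exist for OT), do not cover
dermal uptake, smoking as a covariate, LOD censoring, or
N-acetyltransferase polymorphism, and cannot resolve the forward model's
structural uncertainty — which is why the reconstructed worker doses are
compared to the originally published reverse-dosimetry values only
within a ±35% band, while the closed-form tiers are reproduced exactly.

## Known limitations

* No dermal route: no dermal parameters are published, although dermal
  uptake can contribute substantially to worker exposure; reconstructed
  inhalation-equivalent intakes absorb any dermal contribution.
* The post-shift/steady-state ratio — hence the size of the gap between
  the two tiers (~20% here, ~30–50% in the original assessment) —
  depends on the unpublished reference physiology through the effective
  half-lives; its direction and rough magnitude are robust, its exact
  value is not.
* Exposure within a shift is constant; real intra-shift variability
  would widen the posterior further.
* Strata of the general-population studies are treated as independent
  observations; no hierarchical pooling across studies is attempted.
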