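# Methods

## Scope and model

`transddi` covers the in-vitro-to-in-vivo workflow for transporter-mediated
DDI assessment of a renally secreted victim drug (the bundled case study is
metformin with OCT1/OCT2/MATE1/MATE2-K): uptake-assay normalization,
Michaelis–Menten and dose–response fitting, Caco-2 bidirectional
permeability, and a mechanistic static prediction of AUC change.

The static model is the adapted Rowland–Matin form

    fold-dAUC = 1 / ( fe/(1 + [I]/Ki) + (1 - fe) )

with fe the fraction of total victim clearance attributable to the
inhibitable active renal pathway, [I] the unbound perpetrator Cmax, and Ki
the competitive inhibition constant. Assumptions: competitive inhibition
(Ki = IC50/(1+S/Km), read directly as IC50 when the probe concentration is
at least 10-fold below Km); perpetrator concentration at the transporter
equals unbound plasma Cmax (no intracellular accumulation, appropriate for
passively equilibrating OCT2 substrates); inhibition of a single lumped
OCT2/MATE1 pathway; no change in absorption or non-renal clearance. The
prediction is bounded by 1 ≤ fold-dAUC ≤ 1/(1−fe); both bounds are tested
as closed-form limits.

fe is derived as (renal fraction of total clearance) × (active fraction of
renal clearance), reported at 2 d.p. Two scenarios ship with the bundled
inputs: 0.88 × 0.75 = 0.66 from intravenous mass balance, and
0.52 × 0.75 = 0.39 from oral mass balance. The oral value is the
appropriate one for a flip-flop drug (absorption slower than elimination,
so renal elimination proceeds in parallel with continued absorption), and
the concordance scoring quantifies this: predictions with fe = 0.39 land
within 2–11 percentage points of observed AUC increases versus 39–86
points with fe = 0.66.

Screening ratios follow regulatory static practice: systemic risk when
unbound Cmax/Ki ≥ 0.1; intestinal risk when [I2]/Ki ≥ 10 with
[I2] = dose/(250 mL) in µmol/L. Cut-offs are configuration values.
Reporting conventions (full precision carried internally, rounding only at
reporting): fold-dAUC and fe at 2 d.p., gut ratios to integers, systemic
ratios to 2–3 significant figures.

### Concordance metric

Predicted-vs-observed agreement is scored as the absolute difference of
percent AUC increases, |100·(pred−1) − 100·(obs−1)|, in percentage points,
with predictions entering at their reported 2-d.p. precision. This
definition is the package's design choice for comparing fold-changes near
1–2×; a relative fold error metric (100·|pred−obs|/obs) is available via
`compare_to_observed(..., metric="relative_fold_error")`. Pairing of
prediction rows with clinical studies is keyed on (perpetrator, total
Cmax), matching each study's measured perpetrator exposure.

## Assay processing

Counts are converted as pmol = dpm / SA / f_counted, with SA the dosing
solution's specific activity (37 kBq/mL at 100 µmol/L → 22.2 dpm/pmol via
60 dpm/Bq) and f_counted the counted lysate aliquot fraction (default
300/400 µL; configurable, since published workflows do not always state
whether the aliquot is scaled back). Activities are protein-normalized
(pmol/mg), replicate wells averaged per condition before control
correction, SDs propagated in quadrature. Corrected activity is
transporter-cell minus vector-control mean for the matched condition;
negative corrected values are retained and flagged rather than clamped,
because clamping biases the bottom plateau of inhibition curves.

Linearity of a corrected uptake time course is assessed with a
through-origin least-squares line: the linear window is the longest prefix
of time points with uncentered R² ≥ 0.95 and every point within 15%
relative deviation of the line. The criterion itself is a package design
choice (published work reports linear windows without stating a rule);
both thresholds are parameters.

## Fitting

Michaelis–Menten (v = Vmax·S/(Km+S)) and 4/5-parameter logistic fits use
`scipy.optimize.curve_fit` (trust-region reflective, non-negative bounds),
with asymptotic standard errors from the covariance. Kinetic fits warn on
<4 distinct concentrations, on designs that do not bracket the Km
estimate, and flag Km as unidentifiable when its relative SE exceeds 1
(e.g. saturating-only designs).

Inhibition curves are fitted on log10 concentration as percent of vehicle
control. The symmetric 4PL is y = bottom + (top−bottom)/(1+(x/xmid)^h);
the 5PL multiplies the denominator by a Richards exponent s. The IC50 is
always the concentration where the fitted curve crosses (top+bottom)/2 —
equal to xmid for the 4PL, back-solved as xmid·(2^(1/s)−1)^(1/h) for the
5PL. Model choice under `model="auto"` is by corrected AIC. Numerical
choices: bounds bottom ∈ [−20, 50]%, top ∈ [50, 150]%, hill ∈ (0, 10],
asymmetry ∈ [0.2, 5] (all configurable) stabilize partial curves; starting
values take plateaus from the extreme-concentration means and xmid from
the first concentration crossing half-response; vehicle (zero) wells
anchor the top plateau initialization and stay off the log axis. When no
point falls below 80% control the IC50 is right-censored at the highest
tested concentration. Per-occasion fits are aggregated as arithmetic mean
± SD of occasion-level IC50s (SD undefined for a single occasion); the
fitted optimum is cross-checked in the tests against an exhaustive
(IC50, hill) grid search.

## Permeability

Papp = Q_receiver/(t·A·C0) from the single 90-min end point (the assay
samples receivers once), with C0 µmol/L converted to pmol/cm³; volumes
enter only bookkeeping, not Papp. Mass balance is
100·(receiver + donor-end)/initial donor amount. Monolayer integrity is
per-well: lucifer-yellow Papp ≤ 1.0×10⁻⁶ cm/s, boundary inclusive; failing
wells are excluded from every aggregate. A sink-condition warning fires
when receiver concentration exceeds 10% of donor C0 (standard practice).
The inhibitor-effect test works on log-Papp: fold-change as ratio of
geometric means with a 90% Welch t-interval; "no change" when the interval
lies inside the 0.8–1.25 equivalence band (the bioequivalence convention
for AUC ratios), "change" when it excludes 1, otherwise inconclusive.

## Synthetic data

Generators emulate the real assay designs with exactly known truth:
triplicate transporter/control wells; uptake linear in time with an
optional exponential saturation past a configurable onset (phenomenological
— no intracellular model is claimed); kinetic plates over the real
concentration series (10–10,000 µmol/L); inhibition plates scaled by the
4/5PL value at each inhibitor concentration, with vehicle wells and a
lognormal per-occasion multiplier on the true IC50 (occasion CV default
0.10 in the pipeline, reflecting between-occasion SDs of the case-study
IC50s); transwell plates with Q = Papp·A·C0·t, donor remainder consistent
with a stated recovery, and an independent lucifer-yellow channel
(defaults: 0.12 cm² inserts, 90/210 µL apical/basolateral volumes, 90 min,
Papp 0.5×10⁻⁶ cm/s — paracellular-range permeability).

Noise is multiplicative lognormal on well dpm with a mean-one multiplier
(CV-parameterized); protein per well is truncated-normal (CV 0.05
default). The true noise law of scintillation well data is not known to
the package; lognormal is a flagged stand-in. Contracts tested: identical
seed ⇒ identical output; noise_cv = 0 ⇒ every downstream estimator
recovers truth to ≤0.1%; across 50 seeds the mean fitted Km is within 3
standard errors of truth and the median relative error of Km and IC50 at
noise_cv = 0.05 is ≤10%.

What passing these tests shows — and does not: the pipeline is internally
consistent and unbiased under its own generating model. Real plates add
effects the generator deliberately omits: plate-position and drift
effects, outliers, probe depletion at low Km, proton-gradient dependence
of MATE transport, intracellular accumulation, and micelle/protein binding
in biorelevant matrices (the FaSSIF/HSA matrix is a carried label only).

## Problem sizes

All static-model quantities are desk-scale (20-row grid, milliseconds).
Stochastic test batches use 50 seeded plates per check; the full suite
runs in a few seconds on one CPU.

## Known limitations

No two-site or substrate-inhibition kinetics; no Dixon-style global Ki
fitting; no PBPK/dynamic modelling; no MATE2-K prediction rows (its renal
protein expression is minimal and a selective inhibitor produced no
clinical interaction, so it is excluded from the prediction grid); the
enterocyte concentration Igut,max is accepted only as a supplied constant.
Whether reported between-occasion SDs are occasion-level SDs or pooled-fit
SEs is ambiguous in published tables; the package implements occasion-level
SD.
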