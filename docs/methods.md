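# Methods

## The problem being modelled

An mRNA-LNP product is not the pharmacologically active species: after IV
administration the LNP-formulated mRNA is taken up (predominantly by
hepatocytes), translated into a circulating antibody, and cleared. Human
dose projection therefore has to translate two distinct processes across
species: the kinetics of the mRNA-LNP itself (elimination and translational
efficiency) and the disposition of the translated protein, which behaves
like a conventional therapeutic antibody. The package implements the two
complementary approaches used for this class of molecule: direct allometry
of dose-normalized exposure, and a mechanistic translational model.

## Allometry of dose-normalized exposure

DCmax (1/mL) and DAUC (h/mL) are regressed on body weight through
P = P0·W^α, fitted as ln P = ln P0 + α·ln W by ordinary least squares.
OLS on the log scale is the field standard for allometry and corresponds
to straight lines in log-log exposure-vs-weight plots; we do not use a
weighted nonlinear fit on the original scale. Typical body weights are
0.025 kg (mouse), 0.25 kg (rat), 2.5 kg (NHP) and 70 kg (human).

For single-species prediction a *generalized* exponent is selected by grid
search: candidate exponents (defaults −1.3…−1.0 from mouse, −0.9…−0.6 from
NHP, step 0.01) are each used to predict the human values of every
compound/endpoint pair, and the selected exponent is the one whose
geometric-mean pred/obs ratio is closest to 1 on the log scale. Two metric
variants exist because the ratio convention is genuinely open: the default
uses signed ratios (over- and under-prediction can cancel, which is what
makes the geometric mean an unbiasedness criterion); `folded=True` folds
every ratio to ≥ 1 first (a pure accuracy criterion that cannot cancel).
Joint selection across DCmax and DAUC of all compounds is the default.
Exact ties prefer the exponent nearer the grid midpoint, then the smaller
magnitude; the step of 0.01 is a package convention.

Prediction accuracy is reported as fold error max(r, 1/r) of the ratio
r = pred/obs, with direction; ≤ 2-fold is the conventional acceptance
bound.

## Noncompartmental analysis

* AUC uses the linear-up/log-down trapezoid (the common IV-profile default
  in commercial NCA software): the logarithmic rule on strictly declining
  positive segments, the linear rule otherwise. When an integration limit
  falls inside a sampling segment, the cut point is interpolated *and*
  integrated with that segment's own rule, which makes the area exactly
  additive over adjacent intervals. AUC starts at the first sample of the
  interval; profiles that should include the dosing time must contain a
  t = 0 record.
* λz is the negative slope of ln C vs t over a terminal window. Automatic
  selection scans windows from 3 points up to all points strictly after
  Tmax (Tmax excluded) and keeps the best adjusted R², ties going to the
  longer window. Non-positive slopes yield a "not estimable" flag, never an
  exception. AUC₀₋∞ adds C_last/λz with C_last taken from the regression
  line at t_last by default (switchable to the observed value); the
  extrapolated percentage is reported.
* BLQ observations are excluded from every NCA and likelihood computation;
  they are retained in datasets (flagged, with LLOQ) for plotting.
* Multiple-dose subjects are reduced to the first dosing interval with
  extrapolation to infinity by default (the first dose normalizes DAUC);
  a steady-state mode uses AUC₀₋τ of the last interval instead. Which
  convention the original clinical evaluation used is not reported, so
  both are provided.

## The translational model

States are amounts (µg): mRNA-LNP M, central antibody A1, peripheral
antibody A2. The dose enters M (the structural equations admit no other
input compartment); translation produces antibody at k_translate·M without
consuming M, so total production per unit dose is k_translate/k_elim.
Disposition is a standard 2-compartment model; products showing a single
elimination phase use the 1-compartment variant (V2 and Q absent).

Every structural parameter is base·W^α. Base values are the parameters of
a 1 kg reference animal — reported per-kg units ("1/h/kg", "mL/h/kg") are
read as that power-law coefficient, with W^α applied exactly as in the
structural equations. This reading is stated prominently because per-kg
unit notation is ambiguous; it is the only one consistent with estimating
a separate exponent per parameter.

Default parameter sets (multispecies estimates): RiboMab01 —
k_elim 0.041·W^−0.14 1/h, k_translate 0.27·W^−0.43 1/h, CL 0.28·W^0.79
mL/h, V1 40.1·W, V2 45.6·W mL (fixed to reference-protein estimates),
Q 1.02·W^1.03 mL/h; RiboMab02.1 — k_elim 0.0282·W^−0.042, k_translate
0.043·W^−0.59, CL 7.68·W^0.80, V1 58.4·W (fixed), 1-compartment.

### Numerics

The system is linear with piecewise-constant input, so the default
propagator advances the state exactly between dose-event breakpoints:
x(t+Δ) = e^{AΔ}x + A⁻¹(e^{AΔ}−I)u, with a hard restart at every dose
start/end (bolus = instantaneous jump into M; an infusion is a zero-order
input over its duration; duration 0 is a bolus). `method="ivp"` retains an
adaptive LSODA integration (rtol 1e-8, atol 1e-10 µg) with the same
restarts; it exists as an independent route, and a third route — the
eigendecomposition closed form for a single bolus — is used both as a test
oracle and as the fast path inside the likelihood. The closed form refuses
when any two system eigenvalues are within a relative gap of 1e-8
(coefficients blow up near degeneracy) and callers fall back to the
propagator. Dose-normalized AUC has the volume-free closed form
DAUC = k_tr,eff/(k_elim,eff·CL_eff), used as an exposure oracle throughout.

Percentile bands (10/50/90 by default) are Monte-Carlo over log-normal
parameter multipliers exp(η), η ~ N(0, ω²), 500 replicates by default,
seeded; how the original profile bands were produced is not stated, so
this is the package's own convention.

### Cross-species projection

A fit from one species is projected by multiplying each *effective*
parameter by (W_target/W_source)^exponent. Default exponents: k_elim
−0.10, CL 0.80, V1/V2 1, Q 0.65; k_translate −0.51 when projecting from
mouse but 0 from NHP — translational efficiency per unit body weight falls
with size, and NHP and human are close enough that no adjustment is
warranted. The projected set is returned with all α = 0 (values already
effective at the target weight).

## Estimation

The original analyses used FOCE-I nonlinear mixed-effects estimation on
data that are not publicly available. The package's default estimator is
**pooled maximum likelihood on log concentrations**: log C_obs =
log C_pred + ε, ε ~ N(0, σ²) — the small-σ limit of a proportional error
model — with σ profiled analytically, giving the objective n·log(RSS/n).
No random effects enter the likelihood. This is the single largest
deliberate deviation from the reference methodology; it is justified
because the estimation surface this package must support is recovery of
the *fixed effects* from synthetic data, not replication of mixed-effects
software output. A two-stage mode (per-subject fits, then the log-scale
spread of individual estimates) approximates ω when between-subject
variability is of interest.

Structural values are estimated on the log scale (positive by
construction); exponents are unconstrained. Optimization is L-BFGS-B with
5 seeded starts (the first at the user's initial values, the rest
perturbed by N(0, 0.3) in transformed space); the best objective wins.
Standard errors come from the inverse numeric central-difference Hessian
of −2LL (covariance 2·H⁻¹) mapped through the transforms; RSE% of a
log-estimated value is 100·SE of its log. Failed simulations inside the
objective return a large penalty so the optimizer survives excursions into
non-physical parameter space.

Identifiability guards: exponents require ≥ 2 distinct body weights; the
observation count must be at least the number of free parameters;
single-species fits require all exponents fixed. One genuine ambiguity is
worth knowing: in the 1-compartment variant the profile is bi-exponential
and symmetric under exchanging k_elim with CL/V1 (the classical flip-flop),
so single-species fits should start near the physically expected scale —
the synthetic-data tests do exactly that, and DAUC is invariant under the
swap.

## Synthetic data

The generator is the package's stand-in for the unavailable study data and
defines its test conditions: per subject, structural parameters are
multiplied by exp(η) with η ~ N(0, ω²) per parameter; observations get
proportional noise C_obs = C_pred·(1+ε), ε ~ N(0, σ_prop²), truncated at
zero to honour the literal proportional-error statement (the log-scale
likelihood assumes log-normal noise instead; at the σ used here the
mismatch is second-order, ≈ σ²/2 in mean log, and is asserted by a test).
A warning fires when more than a third of positive-prediction draws
truncate to zero — at that point a proportional error model is no longer
meaningful. The default LLOQ is 1% of the arm's median Cmax (no value is
reported); group sizes (12/species) and dose levels (100 µg/kg) are
package conventions. Seeding uses `SeedSequence` spawning per arm, so arms
are mutually independent and runs are byte-reproducible.

Named designs emulate the modelled programs' sampling schedules:
`bnt141-like` (mouse/rat/NHP/human; human samples at predose, end of
infusion, 3, 6, 24, 48, 72, 168, 336, 504 h), `bnt142-like`
(mouse/NHP/human; predose, EOI, 3, 6, 10, 24, 48, 168 h), `mrna1944-like`
(NHP only). Infusion durations for the clinical regimens are not reported,
so duration is always an explicit input (bolus by default).

What the generator does *not* emulate: assay-specific error structure,
dropout/missingness, immunogenicity on repeat dosing, target-mediated
disposition, or any saturation of hepatic translational capacity. Passing
recovery tests therefore demonstrate internal consistency of the estimator
under the stated statistical model, not robustness to those real-data
features.

## Problem sizes used by the shipped experiments

The recovery experiment uses four species × 12 subjects × 12 sampling
times (1–504 h), single bolus of 100 µg/kg, σ_prop = 0.15, no IIV —
matching the stated study conditions; the replicate-bias property test
runs a reduced version (5 replicates, 4 subjects/species, 8 times, single
start) as the package's choice of routine-test size. The exponent-recovery
experiment uses 200 replicates at the four typical weights with log-normal
CV 10%.

## Known limitations

* Pooled ML understates uncertainty relative to a mixed-effects analysis
  and cannot separate ω from σ; use the two-stage mode for ω.
* BLQ data are excluded, not censored (no M3-style likelihood).
* The model is linear by construction: no translation-capacity saturation,
  no time-varying translation rate, no target-mediated disposition.
* Published observed/predicted tables carry 2–3 significant figures; fold
  errors recomputed from them can differ from printed folds by ~0.01, and
  two printed external-validation folds are mutually inconsistent with
  their own inputs — reports always recompute from the inputs.
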