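# Methods

## Scope and data flow

`neuropbpk` turns transwell permeability assays into rat brain
concentration predictions in four stages: (1) neuroPK parameter derivation,
(2) simulation of a plasma/brain/CSF compartmental model with in vitro → in
vivo scaling factors, (3) estimation of those factors from observed
profiles, and (4) lipophilicity QSPRs plus internal validation. Every unit
is ng / cm³ / s internally; file readers convert once at the boundary (the
permeability tables are stored in the conventional 1e-6 cm/s).

## Transwell analysis

Under sink conditions the cumulative amount in the receiver chamber grows
linearly, `Q(t) = Papp·A·C0·t`. The estimator regresses the
replicate-averaged cumulative amount on time by ordinary least squares with
a free intercept — the intercept absorbs any lag before transport becomes
linear — and divides the slope by `A·C0`. Choices a user can change:

* **Replicate pooling.** Replicates are averaged per time point before the
  fit (default); a per-replicate fit with slope averaging is available and
  identical on balanced designs.
* **Sink guard.** When the transported amount exceeds 10% of the donor load
  (donor volume defaults to 2 cm³) a warning is raised rather than an
  error: the linear model is then an approximation, but short early windows
  often remain usable.
* **Non-positive slopes** (no measurable transport) return a flagged zero
  rather than raising, so batch processing survives inert compounds.
* Sampling-volume replacement corrections are not applied; the assay
  description this package targets does not state sampled volumes.

The derived parameters are `Kp_uu,brain = Papp(A→B)/Papp(B→A)`,
`f_u,brain = Papp(B→A)/Papp(HOM)` and `V_u,brain = V_ECF + V_ICF/f_u,brain`
with water spaces `V_ECF = 0.2`, `V_ICF = 0.6` mL/g (overridable through
`Physiology`).

## The compartmental model

States are the depot amount, plasma, brain-tissue and CSF concentrations,
plus an eliminated-amount ledger added purely so mass conservation is a
testable invariant. Plasma exchanges unbound drug with brain tissue across
the BBB and with CSF across the BCSFB; ECF bulk flow (`Q_bulk`, 0.012
cm³/s) moves unbound drug from tissue to CSF and CSF drainage (`Q_sink`,
0.132 cm³/s) returns it to plasma. Fixed rat physiology: `V_b` 1.28 cm³,
`V_CSF` 0.25 cm³, `S_BBB` 187.5 cm², `S_BCSFB` 0.0375 cm². CSF drug is
treated as fully unbound; plasma and brain unbound concentrations are
`f_u,plasma·C_p` and `SC3·f_u,brain·C_b`. The SC3-scaled unbound brain
concentration is used consistently in both the transport terms and the
observation model — the model defines a single unbound brain concentration,
and using an unscaled variant in the fluxes would make SC3 a pure
observation parameter with different fitted values.

Dosing modes: IV bolus as an initial condition `C_p(0) = D/V_d` (no impulse
term), zero-order infusion active for `D/k_0` seconds — or for the whole
window when only a rate is given — and first-order absorption from a depot
holding the dose. The route is inferred from which parameters a drug
carries: `k_a`+dose → extravascular, `k_0` → infusion, dose alone → bolus.

### Numerics

The system is linear and time-invariant except for the infusion switch, so
two interchangeable solution paths exist:

* `method="ivp"`: LSODA with `rtol = 1e-10`. The absolute tolerance
  auto-scales per state to 1e-9 of the dose-derived scale (amounts: dose;
  concentrations: dose/`V_d`), because a fixed floor in ng/cm³ would
  dominate the CSF compartment, which sits orders of magnitude below
  plasma. Integration restarts at the infusion switch instead of relying on
  event detection, keeping step control honest across the discontinuity.
* `method="analytic"`: exact propagation by the exponential of the
  augmented (constant + forcing) matrix between output times, piecewise
  across the switch. This is both the test oracle and the fast path inside
  optimisation loops (~1 ms per profile evaluation).

The test-suite holds the two paths to 1e-6 relative agreement on random
parameter sets and on all 18 bundled drug × cell-line fixtures, and checks
mass balance to 1e-6 of the dose at every output time.

## Parameter estimation

Fitting is two-stage, mirroring a table structure with one systemic
parameter set per drug but one scaling-factor set per drug × cell line:

1. **Plasma stage** fits `V_d`, `k_el` (and `k_a` for extravascular drugs)
   to the plasma profile with all SCs at 1 — CNS fluxes perturb the plasma
   balance only weakly. `k_a` starts at twice `k_el` when no better value
   exists.
2. **Scaling stage** fixes the systemic parameters and fits `ln SC1..3` by
   bounded trust-region least squares (bounds ±14 in ln-space, covering the
   observed 0.01–2400 range) against all profiles jointly, with a seeded
   5-point log-uniform multi-start because efflux (SC2) and binding (SC3)
   can trade off.

Residuals are relative by default (each residual divided by the observation,
floored at 1e-3 of the profile maximum) so that plasma and brain profiles —
orders of magnitude apart — contribute comparably; log and unweighted
schemes are options. SC3 is held at its initial value (and flagged) when no
brain observation exists, and flagged "weakly identified" when brain data
are unbound-only, since it then trades off against SC2.

### Identifiability

For permeable compounds with large fitted SC2, the brain equilibrates with
plasma on a timescale of seconds (`SC2·Papp(B→A)·S_BBB/V_b` ~ 0.1–1 s⁻¹),
far faster than realistic sampling. The data then pin only the quasi-steady
ratio `SC1/(SC2·SC3)` (plus SC3 itself when both total and unbound brain
observations exist); SC1 individually lies on a nearly flat objective
ridge. Noise-free recovery is still exact — the ridge has a unique
zero-residual point through the weak CSF coupling — and the recovery test
confirms 18/18 truth sets to <5% from SC=1 starts. Under 15% measurement
noise, however, SC1 estimates drift along the ridge: in the bundled
simulation study (100 seeded replicates across the 18 truth sets, sparse
10+8+8-point sampling) the median absolute relative SC1 error is ≈40%.
This is a structural property of the model plus sampling design, not an
estimator artefact; applications needing SC1 itself (rather than the
exposure-determining ratio) would need early post-dose brain sampling or an
informative prior.

## QSPR and internal validation

Per cell line, `ln SC` is regressed on logP by OLS: linear for SC1 and SC2
(monotone trend with lipophilicity), quadratic for SC3 (rise-then-fall,
consistent with the mixed hydrophilic/lipophilic character of brain
homogenate binding). Forms are per-target configuration options. Predicted
factors are `exp(polynomial(logP))`, strictly positive by construction.

The bundled logP values are experimental octanol–water coefficients from
the standard public compilations (PubChem/Hansch): amitriptyline 4.92,
caffeine −0.07, carbamazepine 2.45, fleroxacin 0.24, pefloxacin 0.27,
zolpidem 2.42. With these inputs and the bundled scaling-factor table, five
of the nine QSPRs reach r² ≥ 0.8; the MDCK SC2/SC3 and hCMEC SC1/SC2 fits
do not, driven by the cluster of near-zero-logP compounds whose factors
differ by an order of magnitude (caffeine SC2 = 1 versus fluoroquinolone
SC2 ≈ 13 at logP within 0.35 of it). logP source choice (experimental vs
computed) materially affects these regressions; users with a preferred
descriptor set can substitute their own table.

Internal validation simulates each drug × cell line twice — with fitted and
with QSPR-predicted factors — on a dense grid (241 points over five
elimination half-lives, extended to cover any infusion), extracts brain
C_max and trapezoidal AUC over that window (no extrapolated tail), and
reports `PE% = |ref − pred|/ref·100`. The absolute value is the default
(per-cell-line means aggregate over- and under-prediction); a signed
variant is behind a flag. Means weight the six drugs equally. Because the
QSPR step exponentiates its residuals and brain exposure scales roughly
with `SC1/(SC2·SC3)`, modest ln-space scatter amplifies into large PE%; the
bundled-table validation yields per-cell-line mean PE% between ≈35% (hCMEC)
and ≈150% (MDCK), recomputed on every run by `scripts/acceptance.py` rather
than stored.

## Synthetic data

The generator emulates the two experimental inputs. Transwell runs: exact
sink-condition lines at the standard 15/30/60/90-minute samples, three
replicates, multiplicative noise per sample. In vivo studies: model
simulations at chosen true parameters, sampled at 10 plasma and 8 brain
points log-spaced over five elimination half-lives — the sparse character
of published rat PK studies — with plasma-total, brain-total and
brain-unbound observations by default (the combination that renders SC3
identifiable). Noise is mean-one lognormal with the requested CV
(`sigma² = ln(1+cv²)`), default CV 15% for profiles and 5% for transwell
samples; a proportional-normal option exists. All draws derive from an
explicit integer seed, and CV=0 reproduces the model to solver precision.

What the generator does not emulate: assay-specific error structure
(HPLC calibration, homogenate matrix effects), inter-animal variability,
active/saturable transport, or model misspecification — synthetic-recovery
results therefore demonstrate estimator correctness under the model's own
assumptions, not robustness to biological reality.

## Problem sizes

Default study sizes keep the full test-suite and the acceptance script in
the minutes range on one CPU: 18 noise-free recovery fits plus a 100-replicate
noisy study, 500-seed transwell Monte-Carlo, 241-point validation grids.
All are parameters, not constants.

## Known limitations

* Passive, linear transport only; transporter saturation and active-efflux
  kinetics are folded into the empirical scaling factors, so cell lines
  with strong transporter expression carry drug-dependent biases.
* Single-descriptor QSPRs on six compounds are preliminary by construction.
* SC1 is weakly identified from sparse noisy profiles (see above).
* `V_d`, `k_el` are treated as plasma-identifiable; no mixed-effects or
  Bayesian machinery is provided.
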