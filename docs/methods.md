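# Methods

## The model

`eposim` simulates one ESA-naive haemodialysis patient over 32 weeks on a
daily time step. The state is a ledger of red-blood-cell (RBC) cohorts —
the cells born on each day — plus the dose history. Each day:

1. **Concentration.** The ESA concentration is the superposition of
   mono-exponential decays, one per past dose:
   `C(t) = Σ_d A_d · 2^(−24(t − t_d)/t_half)`, `t_half` in hours, `t` in
   days. Concentration carries dose units (U-equivalents): no absolute
   bioavailability or volume-of-distribution model is attached because only
   the product of sensitivity and the stimulus function is observable.
2. **Production.** The cohort entering circulation on day `t` has mass
   `P(t) = P0 + s · Emax · g(C(t − τ))` with `g(C) = C/(C + C50)`.
   Pre-erythrocyte kinetics are collapsed into the fixed maturation delay
   τ: stimulus felt τ days ago matures into circulation today.
3. **Senescence.** Individual cell lifespans are uniform on
   `[L − Δ, L + Δ]`. A cohort is a large population of such cells, so it
   retires *deterministically* along the survival schedule of that law:
   the expected presence of a cell during the day of age `a` is
   `w(a) = E[clip(ℓ − a, 0, 1)]`, which includes fractional presence on the
   death day and satisfies `Σ_a w(a) = L` exactly. We chose this exact
   mixture over sampling one lifespan per cohort because whole-cohort death
   makes the daily loss a random integer number of cohorts — the untreated
   patient would then drift off their steady state, and conservation and
   steady-state identities would hold only in expectation. The mixture is
   the many-subcohort limit of stratified sampling and keeps those
   identities exact to machine precision; stochasticity remains where the
   study puts it (patient draw, observation noise, bleeding).

**Read-outs.** Haemoglobin is `Hb = κ · (total circulating mass)`; the
mass unit is chosen so κ = 1 g/dL per unit. The reported **mean RBC
lifespan** is the turnover definition: circulating mass divided by the
expected daily senescence loss of the current population, smoothed over a
7-day window (`Σ_i m_i (w(a_i) − w(a_i+7))/7`). At a stationary age
distribution this equals `L` exactly — for any spread with `L − Δ ≥ 7`,
i.e. no cell dies younger than the smoothing window (true for the default
Δ = 15 d) — and it fluctuates with the age distribution whenever past
production was uneven, which is precisely what distinguishes lumpy monthly
dosing from smooth weekly dosing.

**Bleeding** removes the same fraction of every cohort (0–30 % of blood
volume), leaving the normalised age distribution intact; plasma-volume
refill is treated as immediate, so the haemoglobin drop equals the volume
fraction lost. Whether the original tool transiently diluted haemoglobin
before volume restitution is unknown; instantaneous refill is the simpler
convention and only affects the first days after the event.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| target band | 11–12 | g/dL | study target; 13 g/dL safety threshold |
| mean lifespan `L` | 61.2 | days | initial-configuration value of the tool |
| lifespan half-width Δ | 15 | days | not stated anywhere; a realistic dispersion for dialysis patients, and wide enough that the age-structure effects of uneven dosing are visible |
| maturation delay τ | 7 | days | literature-scale erythroblast→reticulocyte lag, collapsed to a pure delay |
| κ (Hb per mass unit) | 1 | g/dL per unit | unit choice, not a physiological constant |
| Emax | 25/61.2 | mass/day | saturated ESA-driven production could sustain 25 g/dL in a median patient: high enough that study-regime dosing sits on the rising, mildly saturating part of the curve and that low-sensitivity patients can still reach target |
| C50 | 6203.85 | U | calibrated (below) |
| sensitivity σ_log | 0.3 | — | log-normal with median 1; gives a ~0.5×–2× interquartile-ish spread of weekly needs, matching the clinical intuition of a few-fold inter-patient variability |
| starting Hb | U{7.0, …, 8.0} | g/dL | uniform over the 11 grid points (the generating law is not stated; uniform is the minimal assumption) |
| observation noise | ±0.5 | g/dL | incidental fluctuation, quantised to the 0.1 g/dL reporting grid before being added so the stated bound is exact; observation-level only, never fed back into the mass balance |
| bleed | week U{18–24}, fraction U[0, 0.30] | — | mode A only |
| session | 12 + 20 | weeks | equilibration + maintenance; the phase boundary is fixed at week 13 whether or not the target was reached |

**Calibration.** C50 is the one free scale of the dose–response. It is
fixed so that the population mean weekly epoetin need — each patient
titrated, noise-free, to hold haemoglobin at 11.5 g/dL with a 24 h
half-life and weekly dosing — is 6,000 U. The per-patient need is solved
from the engine's periodic steady state in closed form: under a constant
dose `D` every `p` days, `C_k = D r^k/(1 − r^p)` on the daily grid
(`r = 2^(−24/t_half)`) and the long-run mean haemoglobin is
`κ L (P0 + s Emax · mean_k g(C_k))` — exact for the engine because total
mass is a lifespan-weighted moving sum of daily production (a test
cross-checks this against a long simulation). Both the per-patient dose
and the outer C50 solve are monotone scalar root-finds (Brent). The
packaged default C50 comes from `calibrate_dose_response` with 2,000
patients, seed 0; `eposim calibrate` re-derives it.

## Session mechanics and conventions

* Weekly arm: 32 dosing opportunities, all weeks visible. Monthly arm:
  weekly dosing/visibility during the 8-week titration window, then weeks
  9, 13, 17, 21, 25, 29 (14 opportunities). "Every two weeks" titration is
  permitted simply by a policy that skips weeks. Hidden weeks are logged
  (true and observed values) but never shown to the policy.
* Order within a week's first day: bleed (if scheduled) → observe → dose.
  Applying the bleed before the observation lets the prescriber react to
  it at the first opportunity.
* Doses are non-negative reals; the bundled policies round to a 250 U
  prescription step because real prescriptions move in steps — this also
  makes the dose-adjustment count meaningful for low-gain policies.
* Randomness: one independent stream per concern (patient, noise, bleed),
  spawned from the session seed, so toggling bleeding does not shift the
  noise draws. All records are byte-reproducible given seeds.
* `summarize` grids: `weekly` uses true weekly haemoglobin (the analysis
  grid); `visible` uses the observed values the prescriber actually saw,
  with trapezoid abscissae at the true week positions. The ability-score
  normalisation `2 − E/N` interpolates the two anchors that define the
  score (all-in-target and all-out-of-target-below-13); the original
  normalisation is not documented, so scores should be compared within
  this package only.

## Scripted prescribers and what the experiments show

Policies are deliberately simple: proportional multiplicative correction
`D ← D · (11.5/Hb_obs)^α` with a dead band, dose rounding, and a 4×
per-administration carry at the switch to monthly dosing (a prescriber
preserving weekly-equivalent exposure). They make no attempt to fit human
behaviour; all cross-arm claims supported here are directional:

* monthly arms require fewer dose adjustments than weekly arms;
* across a gain sweep, adjustment count and maintenance delta Hb correlate
  positively;
* an aggressive first dose overshoots (% Hb > 13) most with the 138 h
  half-life dosed monthly;
* RBC-lifespan variability falls with shorter administration interval and
  longer half-life. This last ordering is probed under exposure-matched
  *constant* dosing (`MatchedConstantPolicy`: each arm's dose solved so its
  periodic steady state sits at 11.5 g/dL), because a titrating controller
  adds feedback-induced cycling that swamps the administration-pattern
  effect; the half-life ordering in weekly arms is read on the daily grid,
  since weekly sampling is synchronous with the 7-day dosing period and
  sees almost none of the within-week ripple.

The synthetic virtual patient emulates: randomized starting anaemia,
few-fold inter-patient sensitivity spread, delayed and saturating dose
response, age-structure-driven haemoglobin dynamics, observation noise and
acute bleeding. It deliberately omits iron availability, inflammation and
hepcidin, endogenous erythropoietin feedback, neocytolysis, route of
administration, missed doses, and inter-individual lifespan/κ variability.
Passing tests therefore validate the simulator's internal mechanics and
the qualitative half-life × interval phenomenology, not quantitative
prediction for real patients.

## Numerical choices and problem sizes

Daily stepping is required to resolve a 24 h half-life (weekly steps alias
it). A 32-week session is 224 daily steps over ≤ ~300 live cohorts
(a few ms). Test-suite experiment grids use 5–40 sessions per condition
and the calibration checks use 150–500 patients; these sizes give the
directional comparisons comfortable margins (verified against larger runs
during development) while keeping the whole suite around five seconds.
Root-finds use Brent's method on provably monotone scalar functions with
expanding brackets; degenerate inputs (empty cohort ledger, zero mass, a
stimulus demand beyond saturation) raise typed errors rather than
returning sentinels.

## Known limitations

* The dose–response functional form, τ, Δ and the score normalisation are
  modelling choices where the original tool's formulas are not public;
  absolute numbers (doses, scores) are comparable within this package only.
* The turnover lifespan read-out needs `L − Δ ≥ 7` d for the exact
  steady-state identity; pathological spreads violating this bias the
  read-out low at equilibrium.
* Human-prescriber phenomena (learning curves, conservatism with long
  half-lives) are out of scope; scripted policies only bound what the
  physiology plus calendar can produce.
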