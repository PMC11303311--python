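# Methods

## Model structure

The model is a deterministic Markov cohort (state-transition) model with
one-month cycles over a 10-year horizon (120 cycles).  Each treatment arm
has its own state space: one progression-free state per dose tier
(`PFS_T0` full dose; `PFS_T1`, `PFS_T2` after the first and second
mandated dose reduction — the letrozole-monotherapy arm has a single
tier), a progressed-disease state `PD`, and an absorbing `DEAD` state.
The cohort enters entirely in `PFS_T0`.  Transitions are unidirectional
in the coarse ordering PFS → PD → DEAD, and dose tiers only step
downward.

Per-state monthly routing (one multinomial row per state, probabilities
used exactly as entered, never renormalized):

| from | to | probability |
|---|---|---|
| `PFS_Tj` | `DEAD` | `p_pfs_death` |
| `PFS_Tj` | `PD` | `p_prog + p_disc` |
| `PFS_T0` | `PFS_T1` | `p_reduce1` |
| `PFS_T1` | `PFS_T2` | `p_reduce2` |
| `PFS_Tj` | `PFS_Tj` | residual |
| `PD` | `DEAD` | `p_pd_death` |

If the explicit outflows of any row exceed one, the arm is rejected with
an error naming the tier — feasibility is enforced by validation, never
by silent rescaling.

**Discontinuation routing.**  Toxicity-driven discontinuation (`p_disc`)
moves the patient to the next treatment line.  Since second-line therapy
is what the `PD` state's cost and utility describe, discontinuation is
routed to `PD`; no separate off-treatment progression-free state exists
in the three-state structure.

**Tier-hop semantics.**  "Dose reduction by one level" is read as the
monthly probability of the T0→T1 hop and "by two levels" as the T1→T2
hop (stepwise reductions, cycle by cycle).  A direct T0→T2 jump within
one cycle is not modeled.

## Accumulation

For cycle k (0-based) with occupancy rows x_k,

* credit under the half-cycle (trapezoidal) correction:
  `credit_k = (x_k + x_{k+1}) / 2`; with the correction off:
  `credit_k = x_{k+1}` (end-of-cycle);
* discount factor: `(1 + r)^(−(k+1)/12)` with annual rate r
  (end-of-cycle timing, the single convention used everywhere);
* cycle cost: `discount · ⟨credit_k, c⟩` with per-state cycle costs c
  (tier costs for PFS tiers, the PD cycle cost, zero for death);
* cycle QALYs: `discount · ⟨credit_k, u_eff⟩ / 12` (one-month cycles
  credit 1/12 year of utility-weighted person-time).

**Adverse-event utility mixture.**  The grade-3/4 adverse-event entries
are absolute health-state utilities, not decrements.  Within a cycle the
utility-bearing events (neutropenia, diarrhea/GI, hepatotoxicity grade
3/4) are treated as mutually exclusive, so every progression-free tier
credits

`u_eff = (1 − Σ_j p_j) · u_pfs + Σ_j p_j · u_j`.

Their monthly probabilities are small (≤ 6%), so ignoring overlap is a
second-order approximation.  QTc-prolongation events carry no utility
value and never enter QALY weighting; they are kept in the inputs for
completeness and future discontinuation-logic extensions.  `PD` credits
`u_pd`; `DEAD` credits zero.

## Rate/probability calculus

Cumulative probabilities and constant hazards are linked by
`p = 1 − exp(−r·t)`; time-base changes go through the hazard scale
(`rescale_prob(p, t1, t2) = 1 − (1−p)^(t2/t1)`).  The 13%/87% split of
total deaths between background incidence and disease progression is
applied on the hazard scale by default — the component hazards then sum
exactly to the total hazard — with a `scale="probability"` mode (direct
fractions of the probability) available since the source of a published
split is often ambiguous.  Note the hazard-scale component
*probabilities* sum to slightly more than the total probability
(1 − e^−x is super-additive over a partition of x); each component is
individually below the total.  The base-case inputs already contain the
per-state death probabilities, so this operation is only needed when
building new arms.

## Key parameters

| parameter | unit | base case | note |
|---|---|---|---|
| horizon | cycles | 120 | 10 years of one-month cycles |
| cycle length | months | 1 | monitoring frequency of the regimens |
| annual discount rate | 1/yr | 0.03 | see below; configurable, scan at {0, 0.03, 0.035} in every base-case report |
| within-cycle correction | – | half_cycle | trapezoidal; `none` selectable |
| willingness-to-pay | QAR/QALY | 448,785 | 1.5× Qatari GDP per capita |
| currency | – | QAR | 1 USD = 3.65 QAR (documentation only; no conversion engine) |

**Discount rate.**  The source evaluation does not state its discount
rate.  3% per year is the conventional base-case rate in
cost-effectiveness practice and is adopted here as the default; because
the choice is not derivable from the published inputs, every base-case
report carries a side table of per-arm totals at 0%, 3% and 3.5%
(`discount_scan.csv`), and the letrozole reproduction check in the test
suite is run at the default.

**Correction variant.**  "Within-cycle corrected" names the standard
half-cycle family without fixing a variant; the trapezoidal average of
adjacent occupancy rows is used, and totals under it are provably
bracketed by the start-of-cycle and end-of-cycle conventions (asserted
in the tests).

## Inputs

The packaged `base_case_inputs.yaml` carries the published per-cycle
costs (QAR, 2022–2023 Qatari payer perspective), utilities and monthly
transition probabilities exactly as printed, including two printed
oddities entered verbatim: the palbociclib 75 mg cycle cost equals the
125 mg cost, and all three abemaciclib tiers share one cost.  The
willingness-to-pay is printed in two variants in the source (448,758 and
448,785 QAR); the methods-section value 448,785 is used.  Hard range
violations (probability outside [0, 1], non-positive cost) fail loading
with an error naming the field; feasibility rules (per-tier outflow ≤ 1,
positive utilities, adverse-event mixture mass < 1, no reductions in a
single-tier arm) are returned as structured diagnostics by
`validate_arm` and enforced before any trace runs.

## Sensitivity analysis

One-way DSA moves each parameter to its low and high bound with all else
at base (endpoint-only evaluation): costs ±15%, utilities and transition
probabilities ±10% or published confidence bounds entered as absolute
bounds (palbociclib PFS utility 0.7387–0.7627, PD utility 0.45–0.55).
Transition/adverse-event probabilities below 1% at base case are
excluded.  A perturbed probability leaving [0, 1] is clipped and the
clip is recorded as a diagnostic on the result row, never applied
silently.

A row's conclusion is **robust** iff the strategy preferred at the
willingness-to-pay is the same at both bounds as at base case, and
**sensitive** otherwise.  Preference is the decision-relevant quantity:
a bound that moves a comparison between "dominated" and "ICER above
WTP" leaves the preferred strategy unchanged and is therefore robust,
which matches how published DSA tables in this literature label such
rows.  The four-way decision class (cost-effective / not /
dominant / dominated) at every bound is retained on each result row.

**Threshold search** bisects a single parameter value between a bracket
whose ends disagree on the preferred strategy, to a relative width of
1e−6, and verifies the flip by evaluating just inside both sides of the
cutoff; a bracket with no disagreement raises a no-crossing error.  On a
one-cycle linear toy model the cutoff provably equals the algebraic
solution of ΔC(x)/ΔE = λ, which the tests assert.

**Tornado** tables rank parameters by the span of the ICER across their
bounds (descending, ties broken alphabetically so the ordering is
invariant under permutation of the input list).  A bound at which the
comparison is dominant/dominated has no ICER; it carries a categorical
flag, the span falls back to the distance of the defined side from the
base-case ICER (zero if neither side is defined), and the plot annotates
the flagged bars instead of fabricating ±∞.

## Synthetic scenarios

`markovcea.scenarios` generates valid random arms from one explicit seed
(no global randomness): costs log-uniform on [500, 50,000] QAR/cycle
with tier costs non-increasing, utilities uniform on (0.3, 0.95],
monthly transition probabilities uniform on [0, 0.1], adverse-event
probabilities uniform on [0, 0.06] — ranges bracketing the base-case
magnitudes by roughly an order of magnitude either way.  Arms are
rejection-sampled until they pass validation (cap 1,000 attempts).  The
generator emulates the *structure* of real arm inputs (valid probability
vectors, positive tiered costs, utilities in range); it does not emulate
correlations between efficacy and toxicity, time-varying hazards, or
patient-level heterogeneity, so passing property tests demonstrates
numerical and logical correctness of the pipeline, not clinical realism.
Closed-form scenarios (immortal full health; a two-state geometric
cohort; a single half-cycle-corrected cycle) pair degenerate inputs with
analytically exact totals and drive the engine-equivalence tests; an
independent per-individual microsimulation (10^6 simulated patients,
fixed seed, end-of-cycle credit) cross-checks the cohort expectation on
seeded synthetic arms within Monte-Carlo error.

## Numerical choices

* Transition-matrix rows must sum to 1 within 1e−12; occupancy rows
  within 1e−10 (checked, not renormalized).
* Probability↔rate roundtrip tolerance 1e−10; exact-identity tolerance
  1e−12 (all tolerances live in `markovcea.constants`).
* Two strategies count as equally effective below 1e−9 QALYs (beneath
  any reporting precision); no ICER is defined there, and with equal
  effectiveness the cheaper strategy is preferred.
* In the cheaper-but-less-effective quadrant the ICER is reported from
  the costlier arm's perspective, and the costlier arm is preferred iff
  that ICER is at or below the willingness-to-pay.
* All internal arithmetic is full double precision; rounding happens
  only in the reporting layer — whole QAR (half away from zero) for
  money, four decimals for QALYs.
* Bisection caps at 80 iterations (a bracket shrinks below any relative
  tolerance ≥ 1e−24 well before that); degenerate inputs (zero-width
  bounds, empty parameter lists, single-arm league tables) raise
  explicit argument errors.

## Known limitations

* The source evaluation was built in TreeAge and does not state its
  discount rate, correction variant, or adverse-event utility mechanics;
  with the conventions above, the letrozole-monotherapy arm reproduces
  the published totals closely (the tests assert agreement within ±10%),
  while the CDK4/6-arm totals — whose published progression-free costs
  imply near-full-dose costing throughout — land lower under the
  stepwise dose-tier semantics implemented here.  Published per-arm
  totals are therefore shipped separately (`reference_results.yaml`) and
  used as fixed inputs for the incremental worked examples.
* Published QALY differences between ribociclib and palbociclib are
  smaller than this reproduction uncertainty, so conclusions that hinge
  on that ordering (dominance vs. cost-saving) can differ from the
  published classification even when the preferred strategy agrees.
* No probabilistic sensitivity analysis, two-way DSA,
  efficiency-frontier sequencing or net-monetary-benefit ranking; no
  time-varying transition probabilities; no survival-curve digitization
  or parametric survival fitting; no currency conversion.
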