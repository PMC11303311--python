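# markovcea

A within-cycle-corrected Markov cohort cost-effectiveness model comparing
the three CDK4/6 inhibitors — palbociclib, ribociclib and abemaciclib,
each combined with letrozole — against letrozole monotherapy in the
first-line treatment of HR+/HER2− advanced breast cancer, from the Qatari
healthcare-payer perspective.  It is written for health-economics and
HTA analysts who want a scriptable, testable Python implementation of
this class of decision model: a cohort trace over
progression-free (PFS) / progressed-disease (PD) / dead states with
mandated dose-reduction tiers, incremental cost-effectiveness analysis,
and one-way deterministic sensitivity analysis with conclusion-flip
threshold search and tornado outputs.

## The model

A cohort enters at full dose in PFS and moves each one-month cycle with
constant monthly probabilities: PFS→PD (progression *p_prog* plus
toxicity-driven discontinuation *p_disc*, which routes to the next
treatment line living in the PD state), PFS→death, PD→death; within PFS,
mandated dose reductions step down one tier at a time
(T0→T1 with *p_red1*, T1→T2 with *p_red2*).  Death is absorbing and all
transitions are unidirectional (PFS→PD→death).  Over a horizon of
T = 120 cycles the discounted totals for each arm are

```
C = Σ_k  (1+r)^(−(k+1)/12) · ⟨credit_k , c⟩
E = Σ_k  (1+r)^(−(k+1)/12) · ⟨credit_k , u⟩ / 12
```

where `credit_k = (x_k + x_{k+1})/2` is the half-cycle (trapezoidal)
state credit for occupancy rows `x_k`, `c` the per-state cycle costs
(QAR) and `u` the per-state utilities; PFS utilities are a
mutually-exclusive mixture of the baseline utility with the grade-3/4
adverse-event utilities.  Strategies are compared by the incremental
cost-effectiveness ratio ICER = ΔC/ΔE against a willingness-to-pay of
λ = 448,785 QAR/QALY (1.5× Qatari GDP per capita), with standard
dominance classification.  Published cumulative probabilities are moved
between time bases on the hazard scale (p = 1 − e^(−rt)), and total
death risk can be split 13%/87% between background incidence and
progression on that same scale.

## Worked example

```python
from markovcea import MarkovCohortCEA

res = MarkovCohortCEA.base_case().fit()
print(res.summary())
```

prints (abridged):

```
Per-arm discounted totals
--------------------------------------------------------
letrozole      cost      101,216 QAR   QALYs 2.1385
palbociclib    cost      841,430 QAR   QALYs 4.2341
ribociclib     cost      706,565 QAR   QALYs 4.1916
abemaciclib    cost      541,503 QAR   QALYs 3.9720

Pairwise comparisons
--------------------------------------------------------
palbociclib vs letrozole: dCost 740,213, dQALY 2.0956, ICER 353,219 QAR/QALY -> cost_effective (prefer palbociclib)
ribociclib vs letrozole: dCost 605,349, dQALY 2.0531, ICER 294,841 QAR/QALY -> cost_effective (prefer ribociclib)
abemaciclib vs letrozole: dCost 440,287, dQALY 1.8335, ICER 240,131 QAR/QALY -> cost_effective (prefer abemaciclib)
palbociclib vs ribociclib: dCost 134,865, dQALY 0.0425, ICER 3,174,126 QAR/QALY -> not_cost_effective (prefer ribociclib)
palbociclib vs abemaciclib: dCost 299,927, dQALY 0.2621, ICER 1,144,333 QAR/QALY -> not_cost_effective (prefer abemaciclib)
ribociclib vs abemaciclib: dCost 165,062, dQALY 0.2196, ICER 751,619 QAR/QALY -> not_cost_effective (prefer abemaciclib)
```

Reading: every CDK4/6 inhibitor plus letrozole buys its extra QALYs below
the 448,785 QAR willingness-to-pay, so each is cost-effective against
letrozole alone; among the inhibitors, ribociclib is preferred over
palbociclib (cheaper, essentially equal effect), and abemaciclib is the
cost-saving choice overall — ribociclib's extra effectiveness would cost
~752k QAR per QALY, above the threshold.

The same workflow is available from the shell:

```bash
markovcea run --config src/markovcea/data/base_case_inputs.yaml --out-dir out/
markovcea dsa --config src/markovcea/data/base_case_inputs.yaml \
    --dsa-spec src/markovcea/data/dsa_ribociclib_vs_abemaciclib.yaml \
    --comparison ribociclib:abemaciclib --out-dir out/
markovcea tornado  ...   # tornado.csv + tornado.svg
markovcea threshold --config ... --path arms.palbociclib.costs.tier0 \
    --comparison ribociclib:palbociclib --lo 10000 --hi 20215.75 --out-dir out/
```

`markovcea run` writes per-arm trace CSVs, the per-arm totals, the
pairwise league table, a discount-rate scan (0% / 3% / 3.5%) and a run
manifest.

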