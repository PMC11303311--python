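# Model input configuration schema (`schema_version: 1`)

A model configuration is a YAML (or JSON-equivalent) mapping:

```yaml
schema_version: 1
settings:
  horizon_cycles: 120          # >= 1 one-month cycles (120 = 10 years)
  cycle_length_months: 1       # cycle length, months
  annual_discount_rate: 0.03   # in [0, 0.2]; end-of-cycle timing
  wcc_method: half_cycle       # half_cycle | none
  wtp: 448785                  # willingness-to-pay, currency per QALY
  currency_label: QAR
arms:
  - name: <arm name>
    costs:                     # per one-month-cycle costs, > 0
      tier0: <full-dose cycle cost>
      tier1: <cost after 1st mandated dose reduction>   # CDK4/6 arms only
      tier2: <cost after 2nd mandated dose reduction>   # CDK4/6 arms only
      pd: <progressed-disease cycle cost>
    utilities:
      pfs: <progression-free utility, (0, 1]>
      pd: <progressed-disease utility, (0, 1]>
      ae:                      # absolute utilities of utility-bearing AEs
        neutropenia_g34: <utility>
        diarrhea_g34: <utility>
        hepatotox_g3: <utility>
        hepatotox_g4: <utility>
        # qtc_480_500 / qtc_gt_500 carry no utility and are omitted here
    probabilities:             # monthly probabilities, all in [0, 1]
      prog: <PFS -> PD>
      pfs_death: <PFS -> death>
      pd_death: <PD -> death>
      reduce1: <tier0 -> tier1 dose reduction>
      reduce2: <tier1 -> tier2 dose reduction>
      disc: <toxicity-driven discontinuation (routes to PD)>
      ae:                      # monthly adverse-event incidences
        neutropenia_g34: <prob>
        diarrhea_g34: <prob>
        hepatotox_g3: <prob>
        hepatotox_g4: <prob>
        qtc_480_500: <prob>
        qtc_gt_500: <prob>
```

Tiers must be contiguous from `tier0`; a single-tier arm (no dose
reductions, e.g. letrozole monotherapy) lists only `tier0` and must have
`reduce1 = reduce2 = 0`.  Hard range violations fail loading with an
error naming the field; feasibility rules (per-tier outflow probability
at most 1, positive utilities, adverse-event mixture mass below 1) are
reported by `markovcea.validate_arm` as structured diagnostics.

## DSA parameter spec

```yaml
parameters:
  - path: arms.ribociclib.costs.tier0   # dot-path into the config
    mode: percent                       # percent | absolute_bounds
    low: -15                            # percent deviations or bound values
    high: 15
    label: "Ribociclib 600 mg cycle cost"
```

`arms.*.<field>` addresses a value shared across arms (it must be equal in
every arm), e.g. `arms.*.utilities.pd`.
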