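# One-way DSA parameter set for the ribociclib-vs-palbociclib comparison:
# drug-acquisition costs +/-15%, utilities and transition probabilities
# +/-10% or published confidence bounds.  Wildcard arm paths address
# values shared across arms (progressed-disease utility, adverse-event
# utilities).
parameters:
  - {path: arms.palbociclib.costs.tier0, mode: percent, low: -15, high: 15,
     label: "Palbociclib 125 mg cycle cost (full dose)"}
  - {path: arms.palbociclib.costs.tier1, mode: percent, low: -15, high: 15,
     label: "Palbociclib 100 mg cycle cost (1-level reduction)"}
  - {path: arms.ribociclib.costs.tier0, mode: percent, low: -15, high: 15,
     label: "Ribociclib 600 mg cycle cost (full dose)"}
  - {path: arms.ribociclib.costs.tier1, mode: percent, low: -15, high: 15,
     label: "Ribociclib 400 mg cycle cost (1-level reduction)"}
  - {path: arms.palbociclib.utilities.pfs, mode: absolute_bounds,
     low: 0.7387, high: 0.7627,
     label: "Utility of PFS (palbociclib), CI bounds"}
  - {path: arms.ribociclib.utilities.pfs, mode: percent, low: -10, high: 10,
     label: "Utility of PFS (ribociclib)"}
  - {path: "arms.*.utilities.pd", mode: absolute_bounds, low: 0.45, high: 0.55,
     label: "Utility of PD, CI bounds"}
  - {path: "arms.*.utilities.ae.neutropenia_g34", mode: percent,
     low: -10, high: 10,
     label: "Utility of grade 3/4 neutropenia"}
  - {path: arms.palbociclib.probabilities.prog, mode: percent,
     low: -10, high: 10, label: "PFS->PD (palbociclib)"}
  - {path: arms.ribociclib.probabilities.prog, mode: percent,
     low: -10, high: 10, label: "PFS->PD (ribociclib)"}
  - {path: arms.palbociclib.probabilities.reduce1, mode: percent,
     low: -10, high: 10, label: "1-level dose reduction (palbociclib)"}
  - {path: arms.ribociclib.probabilities.reduce1, mode: percent,
     low: -10, high: 10, label: "1-level dose reduction (ribociclib)"}
  - {path: arms.palbociclib.probabilities.ae.neutropenia_g34, mode: percent,
     low: -10, high: 10, label: "Grade 3/4 neutropenia (palbociclib)"}
  - {path: arms.ribociclib.probabilities.ae.neutropenia_g34, mode: percent,
     low: -10, high: 10, label: "Grade 3/4 neutropenia (ribociclib)"}
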