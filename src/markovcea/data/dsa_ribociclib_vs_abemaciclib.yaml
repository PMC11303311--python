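# One-way DSA parameter set for the ribociclib-vs-abemaciclib comparison.
parameters:
  - {path: arms.abemaciclib.costs.tier0, mode: percent, low: -15, high: 15,
     label: "Abemaciclib 150 mg BID cycle cost (full dose)"}
  - {path: arms.abemaciclib.costs.tier1, mode: percent, low: -15, high: 15,
     label: "Abemaciclib 100 mg BID cycle cost (1-level reduction)"}
  - {path: arms.ribociclib.costs.tier0, mode: percent, low: -15, high: 15,
     label: "Ribociclib 600 mg cycle cost (full dose)"}
  - {path: arms.ribociclib.costs.tier1, mode: percent, low: -15, high: 15,
     label: "Ribociclib 400 mg cycle cost (1-level reduction)"}
  - {path: arms.abemaciclib.utilities.pfs, mode: percent, low: -10, high: 10,
     label: "Utility of PFS (abemaciclib)"}
  - {path: arms.ribociclib.utilities.pfs, mode: percent, low: -10, high: 10,
     label: "Utility of PFS (ribociclib)"}
  - {path: "arms.*.utilities.pd", mode: absolute_bounds, low: 0.45, high: 0.55,
     label: "Utility of PD, CI bounds"}
  - {path: "arms.*.utilities.ae.neutropenia_g34", mode: percent,
     low: -10, high: 10,
     label: "Utility of grade 3/4 neutropenia"}
  - {path: "arms.*.utilities.ae.diarrhea_g34", mode: percent,
     low: -10, high: 10,
     label: "Utility of grade 3/4 diarrhea / GI events"}
  - {path: arms.abemaciclib.probabilities.prog, mode: percent,
     low: -10, high: 10, label: "PFS->PD (abemaciclib)"}
  - {path: arms.ribociclib.probabilities.prog, mode: percent,
     low: -10, high: 10, label: "PFS->PD (ribociclib)"}
  - {path: arms.abemaciclib.probabilities.reduce1, mode: percent,
     low: -10, high: 10, label: "1-level dose reduction (abemaciclib)"}
  - {path: arms.ribociclib.probabilities.reduce1, mode: percent,
     low: -10, high: 10, label: "1-level dose reduction (ribociclib)"}
  - {path: arms.abemaciclib.probabilities.ae.neutropenia_g34, mode: percent,
     low: -10, high: 10, label: "Grade 3/4 neutropenia (abemaciclib)"}
  - {path: arms.ribociclib.probabilities.ae.neutropenia_g34, mode: percent,
     low: -10, high: 10, label: "Grade 3/4 neutropenia (ribociclib)"}
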