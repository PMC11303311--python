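# Base-case model inputs: published per-cycle costs (QAR, 2022-2023
# Qatari payer perspective), utility values and monthly transition
# probabilities for first-line palbociclib / ribociclib / abemaciclib
# (each with letrozole) versus letrozole monotherapy, entered exactly as
# printed in the source evaluation.
#
# Conventions not stated by the source and fixed here (see docs/methods.md):
# annual discount rate 0.03, trapezoidal half-cycle correction.
schema_version: 1
settings:
  horizon_cycles: 120
  cycle_length_months: 1
  annual_discount_rate: 0.03
  wcc_method: half_cycle
  wtp: 448785            # 1.5x Qatari GDP per capita, QAR per QALY
  currency_label: QAR
arms:
  - name: letrozole
    costs:
      tier0: 2082.25     # letrozole 2.5 mg, no dose reductions
      pd: 3531.52
    utilities:
      pfs: 0.73
      pd: 0.505
      ae:
        neutropenia_g34: 0.72
        diarrhea_g34: 0.70
        hepatotox_g3: 0.77
        hepatotox_g4: 0.77
    probabilities:
      prog: 0.0302
      pfs_death: 0.0049
      pd_death: 0.056
      reduce1: 0
      reduce2: 0
      disc: 0
      ae:
        neutropenia_g34: 0.00059
        diarrhea_g34: 0.0012
        hepatotox_g3: 0.0008
        hepatotox_g4: 0
        qtc_480_500: 0
        qtc_gt_500: 0
  - name: palbociclib
    costs:
      tier0: 20215.75    # 125 mg
      tier1: 18503.83    # 100 mg
      tier2: 20215.75    # 75 mg -- printed identical to the full dose;
                         # plausibly a transcription artifact in the source,
                         # entered as printed (costs are DSA-varied anyway)
      pd: 3531.52
    utilities:
      pfs: 0.7507
      pd: 0.505
      ae:
        neutropenia_g34: 0.72
        diarrhea_g34: 0.70
        hepatotox_g3: 0.77
        hepatotox_g4: 0.77
    probabilities:
      prog: 0.0211
      pfs_death: 0.000779
      pd_death: 0.0067
      reduce1: 0.0107
      reduce2: 0.0066
      disc: 0.0044
      ae:
        neutropenia_g34: 0.04636
        diarrhea_g34: 0.0009
        hepatotox_g3: 0
        hepatotox_g4: 0
        qtc_480_500: 0
        qtc_gt_500: 0
  - name: ribociclib
    costs:
      tier0: 19068.16    # 600 mg
      tier1: 13578.97    # 400 mg
      tier2: 8089.78     # 200 mg
      pd: 3531.52
    utilities:
      pfs: 0.774
      pd: 0.505
      ae:
        neutropenia_g34: 0.72
        diarrhea_g34: 0.70
        hepatotox_g3: 0.77
        hepatotox_g4: 0.77
    probabilities:
      prog: 0.0195
      pfs_death: 0.00031
      pd_death: 0.0091
      reduce1: 0.027
      reduce2: 0.014
      disc: 0.0051
      ae:
        neutropenia_g34: 0.05934
        diarrhea_g34: 0.002
        hepatotox_g3: 0.0051
        hepatotox_g4: 0.0012
        qtc_480_500: 0.002
        qtc_gt_500: 0.0002
  - name: abemaciclib
    costs:
      tier0: 13478.67    # 150 mg BID; all three tiers share one printed cost
      tier1: 13478.67    # 100 mg BID
      tier2: 13478.67    # 50 mg BID
      pd: 3531.52
    utilities:
      pfs: 0.745
      pd: 0.505
      ae:
        neutropenia_g34: 0.72
        diarrhea_g34: 0.70
        hepatotox_g3: 0.77
        hepatotox_g4: 0.77
    probabilities:
      prog: 0.0222
      pfs_death: 0.00191
      pd_death: 0.0058
      reduce1: 0.0183
      reduce2: 0.0092
      disc: 0.0121
      ae:
        neutropenia_g34: 0.01323
        diarrhea_g34: 0.0122
        hepatotox_g3: 0.0034
        hepatotox_g4: 0.0034
        qtc_480_500: 0
        qtc_gt_500: 0
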