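# Published base-case totals of the source evaluation (TreeAge
# implementation), used as fixed inputs for the ICER worked examples and
# as the reference for reproduction checks.  Costs in whole QAR, QALYs at
# the printed precision.
wtp: 448785
arms:
  letrozole:
    total_cost: 100855
    pfs_cost: 54241
    pd_cost: 46614
    total_qaly: 2.093
    pfs_qaly: 1.538
    pd_qaly: 0.555
  palbociclib:
    total_cost: 938439
    pfs_cost: 775171
    pd_cost: 163278
    total_qaly: 4.406
    pfs_qaly: 2.46
    pd_qaly: 1.946
  ribociclib:
    total_cost: 879873
    pfs_cost: 729757
    pd_cost: 150115
    total_qaly: 4.4242
    pfs_qaly: 2.635
    pd_qaly: 1.789
  abemaciclib:
    total_cost: 646941
    pfs_cost: 478210
    pd_cost: 168730
    total_qaly: 4.2225
    pfs_qaly: 2.212
    pd_qaly: 2.010
# Published pairwise ICERs (QAR per QALY gained; for the cheaper-but-
# less-effective quadrant, from the costlier arm's perspective).
icers:
  palbociclib_vs_letrozole: 362120
  ribociclib_vs_letrozole: 334170
  abemaciclib_vs_letrozole: 256438
  palbociclib_vs_abemaciclib: 1588545
  ribociclib_vs_abemaciclib: 1154843
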