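"""Numerical tolerance constants shared across the package.

All tolerances live here so that tests, the engine and the sensitivity
machinery agree on what "equal" means.
"""

#: Tolerance for the probability<->rate roundtrip identity.
TOL_ROUNDTRIP = 1e-10

#: Tolerance for exact-by-construction identities (e.g. p = 1 - exp(-r t)).
TOL_INVARIANT = 1e-12

#: Transition-matrix rows must sum to one within this.
TOL_ROW_SUM = 1e-12

#: Cohort occupancy rows must sum to one within this.
TOL_OCCUPANCY = 1e-10

#: Below this absolute QALY difference two strategies count as equally
#: effective and no ICER is defined (below any reporting precision).
EPS_QALY = 1e-9

#: Below this absolute cost difference (QAR) two strategies count as
#: equally costly.
EPS_COST = 1e-6

#: Months per year, used by the annual-discount -> monthly-cycle conversion.
MONTHS_PER_YEAR = 12.0
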