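"""Summarize inorganic-N dynamics of an incubation into a classified budget.

Endpoint deltas of NH4+, NO2- and NO3- separate three regimes: full
nitrification (nitrate accumulates), nitrite accumulation (the nitrite
oxidizers were filtered out), and no activity.  Production in excess of
ammonium consumption points to mineralization of dissolved organic N.
"""

from throughfall import NSpeciesProfile, summarize_budget

series = [
    NSpeciesProfile("w0", "Cj1", "unfiltered", 0, nh4_uM=174.0, no2_uM=11.0, no3_uM=219.0),
    NSpeciesProfile("w4", "Cj1", "unfiltered", 4, nh4_uM=94.0, no2_uM=0.0, no3_uM=332.0),
]
s = summarize_budget(series)
print(f"dNH4 = {s.delta_nh4:+.0f} uM, dNO2 = {s.delta_no2:+.0f} uM, "
      f"dNO3 = {s.delta_no3:+.0f} uM")
print(f"oxidized N produced = {s.oxidized_n_produced:.0f} uM")
print(f"excess over NH4 consumption = {s.excess_over_nh4_consumption:.0f} uM")
print(f"classification: {s.classification}")

# Expected: dNO3 +113 with only 80 uM of NH4 consumed -> 22 uM of oxidized N
# must have come from mineralized organic N; classification 'nitrifying'.
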