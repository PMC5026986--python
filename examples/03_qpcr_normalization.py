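"""Normalize archaeal amoA qPCR counts to copies per mL with LOQ censoring.

A coarse (10 um) filter that strained 300 mL of throughfall carried
5424 +/- 449 amoA copies; finer filters were below the 44-copies-per-
reaction limit of quantification and must be reported as bounds only.
"""

from throughfall import QpcrAbundance

coarse = QpcrAbundance(
    target="archaeal_amoA", source="Cj1", filter_fraction="f10um",
    copies_per_reaction_mean=5424.0, copies_per_reaction_sd=449.0,
    n_replicates=3, volume_filtered_mL=300.0,
)
fine = QpcrAbundance(
    target="archaeal_amoA", source="Cj1", filter_fraction="f2um",
    copies_per_reaction_mean=30.0, copies_per_reaction_sd=5.0,
    n_replicates=3, volume_filtered_mL=300.0,
)
print(f"10-um filter: {coarse.copies_per_filter:.0f} copies/filter = "
      f"{coarse.copies_per_mL:.1f} +/- {coarse.copies_per_mL_sd:.1f} copies/mL")
print(f"2-um filter: censored={fine.censored}, "
      f"< {fine.per_mL_upper_bound:.2f} copies/mL (LOQ-equivalent bound)")

# Expected: 18.1 copies/mL on the coarse filter — a dilute but real
# ammonia-oxidizer population (below 20 copies/mL); the fine filter yields
# no point value, only the bound.
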