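"""Normalise simulated TLC plates and summarise replicate percentages.

Each plate carries one spot per 5'-cap species plus a saturated origin;
intensities are background-subtracted and expressed as percentages of the
plate total, then averaged over three replicates with a sample SD.
"""

from capscape import SimulationConfig, gen_spot_tables, normalize_plates, replicate_summary

config = SimulationConfig(seed=1, tlc_replicates=3, tlc_noise_sd=0.01)
spots, truth = gen_spot_tables(config)

summary = replicate_summary(normalize_plates(spots))
merged = summary.merge(truth, on=["fraction", "spot_label"])
sub = merged[merged.fraction == "<50"].sort_values("mean", ascending=False)

print("fraction <50 nt, percent of plate total (mean +/- sd over 3 replicates):")
for _, row in sub.iterrows():
    print(f"  {row.spot_label:10s} {row['mean']:5.2f} +/- {row['sd']:4.2f} %  "
          f"(generating truth {row.true_pct:.0f} %)")
print("\nsum of means:", round(sub['mean'].sum(), 6), "%")
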