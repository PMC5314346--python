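# Published constants for the Amazon-basin tree community calibration.
# All numbers come from the large-scale census and occupancy reports the
# calibration is built on; nothing here is fit.
J: 4.3e+11                      # free-standing stems >= 10 cm dbh
area_km2: 6.3e+06
sample_size: 553949             # censused trees
observed_sample_richness: 4962  # species seen in the sample
richness_correction_factor: 1.08  # spatial-correlation bound on the census
constraints:                    # hyperdominant occupancy reports
  - abundance: 3.7e+09          # range covers 7.4% of the basin
    occupancy_fraction: 0.074
  - abundance: 5.0e+09          # range covers 48% of the basin
    occupancy_fraction: 0.48
c1: 1.0                         # range-law prefactor (sensitivity: 0.8-1.2)
a: 3.22                         # interface law c = 1/(a (sigma^2-1) + b)
b: 2.58
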