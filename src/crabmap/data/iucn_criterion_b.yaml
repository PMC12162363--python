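# Geographic-range (Criterion B) thresholds, IUCN Red List Categories and
# Criteria v3.1 — an external standard, kept as data rather than code.
# Units: km². A category applies when the metric is strictly below its bound
# and the required subconditions (fragmentation/decline/fluctuation) are met.
version: "3.1"
b1_eoo_km2:
  CR: 100
  EN: 5000
  VU: 20000
b2_aoo_km2:
  CR: 10
  EN: 500
  VU: 2000
# Near-threatened margin: metrics within this multiple of the VU bound
# (conditions met or unknown) are flagged NT rather than LC.
nt_margin: 1.5
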