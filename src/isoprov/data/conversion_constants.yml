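# Versioned isotope conversion constants.
# Values are transcribed from the cited source publications; they are
# configuration, not code, so alternative calibrations can be swapped in.
version: 1
carbonate_phosphate:
  # d18O_carbonate = slope * d18O_phosphate + intercept (permil VSMOW),
  # all-mammal carbonate-phosphate relation (Iacumin et al. 1996).
  slope: 1.037
  intercept: 8.57
  citation: "Iacumin P. et al. (1996) EPSL 142:1-6, all mammals"
phosphate_water:
  # d18O_phosphate = slope * d18O_drinking_water + intercept (permil VSMOW),
  # deer equation; equivalently d18O_w = 1.23 * d18O_p - 27.09.
  slope: 0.813
  intercept: 22.02
  citation: "D'Angela D. & Longinelli A. (1990) Chem. Geol. 86:75-82, deer"
vpdb_vsmow:
  # d18O_VSMOW = slope * d18O_VPDB + intercept (Coplen 1988).
  slope: 1.03091
  intercept: 30.91
  citation: "Coplen T.B. (1988) Chem. Geol. 72:293-297"
suess:
  loess_span: 0.3
  loess_degree: 2
  ref_year: 1994
  alt_ref_year: 1800
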