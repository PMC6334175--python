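# Example sweep: linear-phase methods across a fixed 200 mm FOV
methods: [MB, MBv, vMB, PINS, MultiPINS]
n_range: [2, 3, 4, 5, 6]
tbp: 4.0
geometry: fixed_fov
fov_mm: 200.0
thickness_mm: 2.0
limits:
  b1_max: 13.0
  g_max: 40.0
  slew_max: 200.0
girf: synthetic
girf_fwhm_khz: 12.0
evaluate_profiles: false
out_csv: sweep_results.csv
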