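# Default acceptance cohort: 10 infected partial-response phantom larvae,
# seeds 0-9, default contrasts (anterior 14x, posterior 5x the middle),
# imaged under the default light-sheet intensity field and flat-fielded
# against a simulated uniform-fluorescence reference.
seed: 0
outdir: larvalight_out
mode: snapshot
n_larvae: 10
flatfield: true
radius_px: 6
n_bins: 14
phantom:
  sheet_field:
    I0: 100.0
    xc: 450.0
    xR: 600.0
    yc: 110.0
    sigma_y: 180.0
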