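# Full pipeline run on the default phantom.
# All blocks are optional; shown values are the defaults.
outdir: demo_run
seed: 1
phantom:
  noise: 0.2              # multiplicative speckle amplitude
  # cap_thickness_field: {kind: gaussian_dip, params: {base_um: 300.0, min_um: 100.0}}
view_angles: [0.0, 90.0]
grid:
  ds_mm: 0.2
  dtheta_deg: 10.0
segmentation:
  smoothness: 0.5
  max_step: 2
thresholds:
  t_cap_um: 151.0
  t_wss_pa: 1.7
area_frame_stride: 4      # lumen-area frames outside the plaque ROI
sensitivity: true
# external_wss: cfd_samples.csv   # replaces the analytic surrogate
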