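# Demo pipeline configuration: two-lumen dissection phantom at
# acquisition-like settings (2.5 mm isotropic, 20 cardiac phases),
# 60/40 TL/FL flow split with 30% retrograde false-lumen volume,
# stent-like noise injected and excised by the preprocessing stage.
seed: 7
phantom:
  kind: dissection
  spec:
    geometry: straight-tube
    radius_mm: 12.0
    spacing_mm: 2.5
    n_phases: 20
    waveform: systolic-pulse
    noise_sd_ms: 0.05
    length_mm: 140.0
  dissection:
    tl_fraction: 0.6
    fl_reverse_fraction: 0.3
    total_volume_ml: 70.0
  stent:
    enabled: true
    n_voxels: 50
    amplitude_ms: 2.0
preprocess:
  threshold: auto
centerline:
  resample_mm: 1.0
  smooth_mm: 5.0
  prune_mm: 5.0
  section_radius_mm: 30.0
  close_radius_vox: 1
quantify:
  stasis_threshold_ms: 0.1
helicity:
  include_boundary: false
  projection_axis: x
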