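# RNAscope reference scene (desk-scale): viremic lymph node with
# cell-associated vRNA (CD4dim rate higher in EF than F; within F, higher
# in CD4dim than CD4hi) and FDC-bound virions (30 then 10 per follicle).
panel: rnascope
scene:
  field_size: [800, 800]
  pixel_size: 0.5
  seed: 1
  n_follicles: 4
  follicle_margin: 45
  follicle_axes_range: [95, 120]
  follicle_axis_ratio: [0.75, 0.95]
  gc_fraction: 0.40
  dz_fraction: 0.45
  cell_density: 8000
  nucleus_radius: [3.0, 0.35]
  fdc_density: 0.25
  composition:
    LZ: {Tcd4hi: 0.10, Tcd4dim: 0.05, Tcd8: 0.01, Other: 0.84}
    DZ: {Tcd4hi: 0.10, Tcd4dim: 0.05, Tcd8: 0.01, Other: 0.84}
    MZ: {Tcd4hi: 0.10, Tcd4dim: 0.05, Tcd8: 0.01, Other: 0.84}
    EF: {Tcd4hi: 0.30, Tcd4dim: 0.10, Tcd8: 0.15, Other: 0.45}
  phenotype_profiles:
    Tcd4hi:  {CD3: [220, 0.25], CD4: [220, 0.25]}
    Tcd4dim: {CD3: [220, 0.25], CD4: [45, 0.25]}
    Tcd8:    {CD3: [220, 0.25]}
    Other:   {}
  vrna:
    cell_assoc_rate:
      Tcd4dim: {EF: 0.16, F: 0.08}
      Tcd4hi: {EF: 0.02, F: 0.05}
    fdc_bound_count: [30, 10]
    punctum_radius: 0.5
    punctum_level: 350
    extra_puncta_mean: 1.5
optics:
  psf_sigma: 0.4
  autofluorescence: 2.0
  noise: {gaussian_sd: 1.5, poisson_scale: 1.0}
  bit_depth: 16
pipeline:
  segmentation: {smooth_sigma: 0.4, peak_min_distance: 1.5}
  features: {intensity_erosion: 0.0}
  compartment:
    density_sigma: 10.0
    cd20_threshold: 0.40
    gc_opening: 2.0
    min_follicle_area: 8000
  spots: {log_sigma_range: [0.35, 0.9], threshold: 15.0, min_separation: 0.6}
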