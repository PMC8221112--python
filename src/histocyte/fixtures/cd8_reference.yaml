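# CD8-panel reference scene (desk-scale): CD8bright cells mainly
# extrafollicular; follicular CD8 rare with mostly GrzB-/FasL- phenotype.
panel: cd8
scene:
  field_size: [500, 500]
  pixel_size: 0.5
  seed: 1
  n_follicles: 2
  follicle_axes_range: [80, 105]
  follicle_axis_ratio: [0.70, 0.95]
  gc_fraction: 0.35
  dz_fraction: 0.45
  cell_density: 8000
  nucleus_radius: [3.0, 0.35]
  composition:
    LZ: {B_lz: 0.82, CD4T: 0.05, CD8T: 0.008, CD8Grz: 0.001, CD8FasL: 0.001, Other: 0.12}
    DZ: {B_dz: 0.82, CD4T: 0.05, CD8T: 0.008, CD8Grz: 0.001, CD8FasL: 0.001, Other: 0.12}
    MZ: {B_mz: 0.75, CD4T: 0.07, CD8T: 0.01, Other: 0.17}
    EF: {B_ef: 0.06, CD4T: 0.28, CD8T: 0.12, CD8Grz: 0.02, CD8FasL: 0.01, CD8DP: 0.005, Other: 0.505}
  phenotype_profiles:
    B_mz:    {CD20: [60, 0.25]}
    B_lz:    {CD20: [220, 0.25], Ki67: [40, 0.25]}
    B_dz:    {CD20: [60, 0.25], Ki67: [220, 0.25]}
    B_ef:    {CD20: [220, 0.25]}
    CD4T:    {CD4: [200, 0.25]}
    CD8T:    {CD8: [250, 0.25]}
    CD8Grz:  {CD8: [250, 0.25], GrzB: [200, 0.25]}
    CD8FasL: {CD8: [250, 0.25], FasL: [200, 0.25]}
    CD8DP:   {CD8: [250, 0.25], GrzB: [200, 0.25], FasL: [200, 0.25]}
    Other:   {}
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
    gc_threshold: 0.06
    gc_closing: 8.0
    ki67_threshold: 0.5
    gc_opening: 2.0
    min_follicle_area: 8000
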