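# B-cell-immunity reference scene (desk-scale): follicular B subsets with
# plasma cells (CD38hiCD138hi) enriched extrafollicularly and a small
# pH2Ax+ GC fraction.
panel: bcell
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
    LZ: {B_lz: 0.80, B_ph: 0.03, CD4T: 0.05, PC: 0.005, Other: 0.115}
    DZ: {B_dz: 0.78, B_ph_dz: 0.05, CD4T: 0.05, PC: 0.005, Other: 0.115}
    MZ: {B_mz: 0.75, CD4T: 0.075, PC: 0.01, Other: 0.165}
    EF: {B_ef: 0.06, CD4T: 0.30, PC: 0.05, Other: 0.59}
  phenotype_profiles:
    B_mz:    {CD20: [60, 0.25], CD38: [40, 0.25]}
    B_lz:    {CD20: [220, 0.25], Ki67: [40, 0.25], Bcl6: [200, 0.25], CD38: [40, 0.25]}
    B_dz:    {CD20: [60, 0.25], Ki67: [220, 0.25], Bcl6: [200, 0.25], CD38: [40, 0.25]}
    B_ph:    {CD20: [220, 0.25], Ki67: [40, 0.25], Bcl6: [200, 0.25], CD38: [40, 0.25], pH2Ax: [200, 0.25]}
    B_ph_dz: {CD20: [60, 0.25], Ki67: [220, 0.25], Bcl6: [200, 0.25], CD38: [40, 0.25], pH2Ax: [200, 0.25]}
    B_ef:    {CD20: [220, 0.25], CD38: [40, 0.25]}
    PC:      {CD38: [300, 0.25], CD138: [220, 0.25]}
    CD4T:    {CD4: [200, 0.25]}
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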