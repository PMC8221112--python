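# Inflammation-panel reference scene.  CD163loCD68hi macrophages at 1.85%
# of EF cells, 1.1% of GC cells (and ~1.8% of whole-follicle cells via the
# mantle-zone share), with the other monocytic subsets and MPOhi
# neutrophils predominantly extrafollicular.
panel: inflammation
scene:
  field_size: [1100, 1100]
  pixel_size: 0.5
  seed: 1
  n_follicles: 9
  follicle_axes_range: [110, 160]
  follicle_axis_ratio: [0.70, 0.95]
  gc_fraction: 0.45
  dz_fraction: 0.45
  cell_density: 10000
  nucleus_radius: [3.0, 0.35]
  composition:
    LZ: {B_lz: 0.83, CD4T: 0.03, Tfh: 0.013, MacM1: 0.011, MacM2: 0.001, MacDP: 0.001, Neut: 0.0005, Other: 0.1135}
    DZ: {B_dz: 0.83, CD4T: 0.03, Tfh: 0.013, MacM1: 0.011, MacM2: 0.001, MacDP: 0.001, Neut: 0.0005, Other: 0.1135}
    MZ: {B_mz: 0.73, CD4T: 0.07, MacM1: 0.0239, MacM2: 0.004, MacDP: 0.002, Neut: 0.003, Other: 0.1671}
    EF: {B_ef: 0.06, CD4T: 0.30, Tfh: 0.002, MacM1: 0.0185, MacM2: 0.02, MacDP: 0.012, Neut: 0.025, Other: 0.5625}
  phenotype_profiles:
    B_mz:  {CD20: [60, 0.25]}
    B_lz:  {CD20: [220, 0.25], Ki67: [40, 0.25]}
    B_dz:  {CD20: [60, 0.25], Ki67: [220, 0.25]}
    B_ef:  {CD20: [220, 0.25]}
    CD4T:  {CD4: [200, 0.25], PD1: [18, 0.3]}
    Tfh:   {CD4: [200, 0.25], PD1: [220, 0.25]}
    MacM1: {CD68: [220, 0.25]}
    MacM2: {CD163: [220, 0.25]}
    MacDP: {CD68: [220, 0.25], CD163: [220, 0.25]}
    Neut:  {MPO: [250, 0.25]}
    Other: {}
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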