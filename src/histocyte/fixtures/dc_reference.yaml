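# DC-panel reference scene.  CD11c+ events at 1.0% of GC cells and ~2% of
# whole-follicle cells; CD11c-CD123+ and CD11c+CLEC9A+ events rare (<0.3%)
# inside GCs and enriched extrafollicularly/perifollicularly.
panel: dc
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
    LZ: {B_lz: 0.83, CD4T: 0.04, CD8T: 0.005, mDC: 0.008, cDC9A: 0.002, pDC: 0.001, Other: 0.114}
    DZ: {B_dz: 0.83, CD4T: 0.04, CD8T: 0.005, mDC: 0.008, cDC9A: 0.002, pDC: 0.001, Other: 0.114}
    MZ: {B_mz: 0.72, CD4T: 0.06, CD8T: 0.01, mDC: 0.023, cDC9A: 0.0052, pDC: 0.004, Other: 0.1778}
    EF: {B_ef: 0.06, CD4T: 0.30, CD8T: 0.12, mDC: 0.025, cDC9A: 0.008, pDC: 0.01, Other: 0.477}
  phenotype_profiles:
    B_mz:  {CD20: [60, 0.25]}
    B_lz:  {CD20: [220, 0.25], Ki67: [40, 0.25]}
    B_dz:  {CD20: [60, 0.25], Ki67: [220, 0.25]}
    B_ef:  {CD20: [220, 0.25]}
    CD4T:  {CD4: [200, 0.25]}
    CD8T:  {CD8: [250, 0.25]}
    mDC:   {CD11c: [220, 0.25]}
    cDC9A: {CD11c: [220, 0.25], CLEC9A: [200, 0.25]}
    pDC:   {CD123: [220, 0.25]}
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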