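# GC-microarchitecture reference scene (desk-scale): IgD+ naive B mantle,
# FDC meshwork confined to GCs, collagen/vasculature in EF space.
panel: structure
scene:
  field_size: [600, 600]
  pixel_size: 0.5
  seed: 1
  n_follicles: 3
  follicle_axes_range: [80, 110]
  follicle_axis_ratio: [0.70, 0.95]
  gc_fraction: 0.35
  dz_fraction: 0.45
  cell_density: 8000
  nucleus_radius: [3.0, 0.35]
  fdc_density: 0.25
  composition:
    LZ: {B_lz: 0.85, Endo: 0.001, Fibro: 0.004, Other: 0.145}
    DZ: {B_dz: 0.85, Endo: 0.001, Fibro: 0.004, Other: 0.145}
    MZ: {B_mz: 0.80, Endo: 0.01, Fibro: 0.03, Other: 0.16}
    EF: {B_ef: 0.06, Endo: 0.05, Fibro: 0.12, Other: 0.77}
  phenotype_profiles:
    B_mz:  {CD20: [60, 0.25], IgD: [220, 0.25]}
    B_lz:  {CD20: [220, 0.25], Ki67: [40, 0.25]}
    B_dz:  {CD20: [60, 0.25], Ki67: [220, 0.25]}
    B_ef:  {CD20: [220, 0.25]}
    Endo:  {CD31: [220, 0.25], Collagen: [220, 0.25]}
    Fibro: {Collagen: [220, 0.25]}
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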