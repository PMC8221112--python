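# GC-reactivity reference scene.  Ground-truth compositions encode the
# tonsillar GC populations this panel quantifies: ~83% B cells, 5.8% total
# CD4 T cells of which 4.0% of GC cells are Tfh (PD-1hi) and 0.03% Tfr
# (FoxP3+), with a mantle-zone CD4 share chosen so that Tfh are 20% of
# whole-follicle CD4 and 69% of GC-only CD4.
panel: gc_reactivity
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
    LZ: {B_lz: 0.83, CD4T: 0.0177, Tfh: 0.028, Tfh57: 0.012, Tfr: 0.0003, Other: 0.112}
    DZ: {B_dz: 0.83, CD4T: 0.0177, Tfh: 0.028, Tfh57: 0.012, Tfr: 0.0003, Other: 0.112}
    MZ: {B_mz: 0.756, CD4T: 0.1152, Treg: 0.001, Other: 0.1278}
    EF: {B_ef: 0.06, CD4T: 0.12, Treg: 0.002, Other: 0.818}
  phenotype_profiles:
    B_mz:  {CD20: [60, 0.25]}
    B_lz:  {CD20: [220, 0.25], Ki67: [40, 0.25], Bcl6: [200, 0.25]}
    B_dz:  {CD20: [60, 0.25], Ki67: [220, 0.25], Bcl6: [200, 0.25]}
    B_ef:  {CD20: [220, 0.25]}
    CD4T:  {CD4: [200, 0.25], PD1: [18, 0.3]}
    Tfh:   {CD4: [200, 0.25], PD1: [220, 0.25], Bcl6: [120, 0.25]}
    Tfh57: {CD4: [200, 0.25], PD1: [220, 0.25], Bcl6: [120, 0.25], CD57: [200, 0.25]}
    Tfr:   {CD4: [200, 0.25], FoxP3: [180, 0.25], PD1: [40, 0.3]}
    Treg:  {CD4: [200, 0.25], FoxP3: [180, 0.25]}
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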