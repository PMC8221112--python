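# T-cell-regulation reference scene.  Encodes the rarity structure of
# regulatory populations: follicular CD25hiFoxP3+ Tfr ~0.1% of pooled
# follicular cells (printed bound 0.2%), CD25+FoxP3+ Tregs ~1.4% of
# T-cell-zone CD4 (bound 2%), and CD25hiFoxP3+IL10hi cells ~0.3% of
# extrafollicular CD4 T cells.
panel: treg
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
    LZ: {B_lz: 0.83, CD4T: 0.05, Treg: 0.0005, TregHel: 0.0002, TregIL10: 0.0001, Other: 0.1192}
    DZ: {B_dz: 0.83, CD4T: 0.05, Treg: 0.0005, TregHel: 0.0002, TregIL10: 0.0001, Other: 0.1192}
    MZ: {B_mz: 0.756, CD4T: 0.075, Treg: 0.0008, TregHel: 0.0002, TregIL10: 0.0002, Other: 0.1678}
    EF: {B_ef: 0.06, CD4T: 0.33, Treg: 0.003, TregHel: 0.0008, TregIL10: 0.00104, HelTreg: 0.0002, Other: 0.60496}
  phenotype_profiles:
    B_mz:     {CD20: [60, 0.25]}
    B_lz:     {CD20: [220, 0.25], Ki67: [40, 0.25]}
    B_dz:     {CD20: [60, 0.25], Ki67: [220, 0.25]}
    B_ef:     {CD20: [220, 0.25]}
    CD4T:     {CD4: [200, 0.25]}
    Treg:     {CD4: [200, 0.25], CD25: [200, 0.25], FoxP3: [180, 0.25]}
    TregHel:  {CD4: [200, 0.25], CD25: [200, 0.25], FoxP3: [180, 0.25], Helios: [180, 0.25]}
    TregIL10: {CD4: [200, 0.25], CD25: [200, 0.25], FoxP3: [180, 0.25], IL10: [200, 0.25]}
    HelTreg:  {CD4: [200, 0.25], CD25: [200, 0.25], Helios: [180, 0.25]}
    Other:    {}
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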