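# CD8 T-cell positioning/function panel: CD8^bright CTL subsets by
# granzyme B and FasL, against the CD20/Ki67/CD4 tissue scaffold.
name: cd8
channels:
  - {name: DNA,  localization: nuclear}
  - {name: Ki67, localization: nuclear}
  - {name: FasL, localization: surface}
  - {name: CD8,  localization: surface}
  - {name: GrzB, localization: surface}
  - {name: CD20, localization: surface}
  - {name: CD57, localization: surface}
  - {name: CD4,  localization: surface}
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [FasL, CD8, 0.08]
  - [CD8, FasL, 0.04]
  - [GrzB, CD20, 0.07]
  - [CD20, GrzB, 0.04]
  - [CD57, CD4, 0.06]
  - [CD4, CD57, 0.04]
thresholds:
  CD20: {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67: {method: gmm_edge, levels: 3}
  CD4:  {method: gmm_edge, levels: 2, n_components: 3}
  CD8:  {method: gmm_edge, levels: 2, n_components: 3}
  GrzB: {method: gmm_edge, levels: 2, n_components: 3}
  FasL: {method: gmm_edge, levels: 2, n_components: 3}
  CD57: {method: gmm_edge, levels: 2, n_components: 3}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: CD4, parent: all, terms: [[CD4, "+"]]}
  - {name: CD8bright, parent: all, terms: [[CD8, hi]]}
  - {name: CD8_GrzB, parent: CD8bright, terms: [[GrzB, "+"]]}
  - {name: CD8_FasL, parent: CD8bright, terms: [[FasL, "+"]]}
  - {name: CD8_GrzB_FasL, parent: CD8bright, terms: [[GrzB, "+"], [FasL, "+"]]}
quantification:
  - {population: CD8bright, scope: EF}
  - {population: CD8bright, scope: F}
  - {population: CD8bright, scope: GC}
  - {population: CD8_GrzB, scope: GC}
  - {population: CD8_FasL, scope: GC}
  - {population: CD8_GrzB_FasL, scope: GC}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
  tzone_marker: CD4
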