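# Dendritic-cell panel: myeloid DC (CD11c+), cross-presenting DC
# (CD11c+CLEC9A+CD123-) and plasmacytoid DC (CD11c-CD123+CLEC9A-).
name: dc
channels:
  - {name: DNA,    localization: nuclear}
  - {name: Ki67,   localization: nuclear}
  - {name: CD11c,  localization: surface}
  - {name: CD123,  localization: surface}
  - {name: CLEC9A, localization: surface}
  - {name: CD20,   localization: surface}
  - {name: CD4,    localization: surface}
  - {name: CD8,    localization: surface}
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [CD11c, CD123, 0.08]
  - [CD123, CD11c, 0.05]
  - [CLEC9A, CD20, 0.07]
  - [CD20, CLEC9A, 0.04]
  - [CD4, CD8, 0.06]
  - [CD8, CD4, 0.04]
thresholds:
  CD20:   {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67:   {method: gmm_edge, levels: 3}
  CD4:    {method: gmm_edge, levels: 2, n_components: 3}
  CD8:    {method: gmm_edge, levels: 2, n_components: 3}
  CD11c:  {method: gmm_edge, levels: 2, n_components: 3}
  CD123:  {method: gmm_edge, levels: 2, n_components: 3}
  CLEC9A: {method: gmm_edge, levels: 2, n_components: 3}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: CD4, parent: all, terms: [[CD4, "+"]]}
  - {name: CD8, parent: all, terms: [[CD8, "+"]]}
  - {name: CD11c, parent: all, terms: [[CD11c, "+"]]}
  - {name: DC_CLEC9A, parent: CD11c, terms: [[CLEC9A, "+"], [CD123, "-"]]}
  - {name: pDC, parent: all, terms: [[CD123, "+"], [CD11c, "-"], [CLEC9A, "-"]]}
quantification:
  - {population: CD11c, scope: GC}
  - {population: CD11c, scope: F}
  - {population: DC_CLEC9A, scope: GC}
  - {population: pDC, scope: GC}
  - {population: CD11c, scope: F, per_follicle: true}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
  tzone_marker: CD4
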