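# Monocyte/inflammation panel: neutrophils (MPO^hi) and monocyte/macrophage
# subsets by CD163/CD68 co-expression, mapped against GC and Tfh positioning.
name: inflammation
channels:
  - {name: DNA,   localization: nuclear}
  - {name: Ki67,  localization: nuclear}
  - {name: MPO,   localization: surface}
  - {name: CD68,  localization: surface}
  - {name: PD1,   localization: surface}
  - {name: CD20,  localization: surface}
  - {name: CD163, localization: surface}
  - {name: CD4,   localization: surface}
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [MPO, CD68, 0.09]
  - [CD68, MPO, 0.05]
  - [PD1, CD20, 0.09]
  - [CD20, PD1, 0.04]
  - [CD163, CD4, 0.07]
  - [CD4, CD163, 0.04]
thresholds:
  CD20:  {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67:  {method: gmm_edge, levels: 3}
  CD4:   {method: gmm_edge, levels: 2, n_components: 3}
  PD1:   {method: gmm_edge, levels: 3}
  MPO:   {method: gmm_edge, levels: 2, n_components: 3}
  CD68:  {method: gmm_edge, levels: 2, n_components: 3}
  CD163: {method: gmm_edge, levels: 2, n_components: 3}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: CD4, parent: all, terms: [[CD4, "+"]]}
  - {name: Tfh, parent: CD4, terms: [[PD1, hi]]}
  - {name: MPOhi, parent: all, terms: [[MPO, hi]]}
  - {name: Mac_CD163hi_CD68lo, parent: all, terms: [[CD163, "+"], [CD68, "-"]]}
  - {name: Mac_CD163lo_CD68hi, parent: all, terms: [[CD68, "+"], [CD163, "-"]]}
  - {name: Mac_CD163hi_CD68hi, parent: all, terms: [[CD163, "+"], [CD68, "+"]]}
quantification:
  - {population: Mac_CD163lo_CD68hi, scope: EF}
  - {population: Mac_CD163lo_CD68hi, scope: F}
  - {population: Mac_CD163lo_CD68hi, scope: GC}
  - {population: Mac_CD163hi_CD68lo, scope: EF}
  - {population: Mac_CD163hi_CD68hi, scope: EF}
  - {population: MPOhi, scope: EF}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
  tzone_marker: CD4
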