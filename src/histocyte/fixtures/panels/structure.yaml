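# GC microarchitecture panel: naive B cells (IgD), FDC meshwork, collagen
# and vasculature (CD31+Collagen) for structural area quantification.
name: structure
channels:
  - {name: DNA,      localization: nuclear}
  - {name: Ki67,     localization: nuclear}
  - {name: CD31,     localization: surface}
  - {name: IgD,      localization: surface}
  - {name: CD20,     localization: surface}
  - {name: FDC,      localization: surface}
  - {name: Collagen, localization: surface}
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [CD31, IgD, 0.08]
  - [IgD, CD31, 0.04]
  - [CD20, FDC, 0.06]
  - [FDC, CD20, 0.04]
  - [Collagen, CD31, 0.05]
thresholds:
  CD20: {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67: {method: gmm_edge, levels: 3}
  IgD:  {method: gmm_edge, levels: 2}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: B_naive_IgD, parent: B, terms: [[IgD, hi]]}
quantification:
  - {population: B_naive_IgD, scope: F, denominator: B}
  - {population: B, scope: F}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
structural_markers: {fdc: FDC, collagen: Collagen, cd31: CD31, igd: IgD}
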