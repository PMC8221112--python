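# B-cell immunity panel: follicular B subsets (Ki67/Bcl-6), plasma cells
# (CD38hiCD138hi) and DNA-damage signal (pH2Ax) on large (live) events.
name: bcell
channels:
  - {name: DNA,   localization: nuclear}
  - {name: Ki67,  localization: nuclear}
  - {name: CD138, localization: surface}
  - {name: CD38,  localization: surface}
  - {name: Bcl6,  localization: nuclear}
  - {name: CD20,  localization: surface}
  - {name: pH2Ax, localization: nuclear}
  - {name: CD4,   localization: surface}
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [CD138, CD38, 0.08]
  - [CD38, CD138, 0.04]
  - [Bcl6, CD20, 0.06]
  - [CD20, Bcl6, 0.04]
  - [pH2Ax, CD4, 0.07]
  - [CD4, pH2Ax, 0.03]
thresholds:
  CD20:  {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67:  {method: gmm_edge, levels: 3}
  CD4:   {method: gmm_edge, levels: 2, n_components: 3}
  Bcl6:  {method: gmm_edge, levels: 2}
  CD38:  {method: gmm_edge, levels: 3}
  CD138: {method: gmm_edge, levels: 2, n_components: 3}
  pH2Ax: {method: gmm_edge, levels: 2, n_components: 3}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: B_Ki67neg, parent: B, terms: [[Ki67, "-"]]}
  - {name: B_Ki67pos, parent: B, terms: [[Ki67, "+"]]}
  - {name: B_Ki67pos_Bcl6hi, parent: B_Ki67pos, terms: [[Bcl6, "+"]]}
  - {name: B_Ki67pos_Bcl6lo, parent: B_Ki67pos, terms: [[Bcl6, "-"]]}
  - {name: B_pH2Ax_Volhi, parent: B, terms: [[pH2Ax, "+"], [volume, hi]]}
  - {name: PC, parent: all, terms: [[CD38, hi], [CD138, "+"]]}
  - {name: CD4, parent: all, terms: [[CD4, "+"]]}
quantification:
  - {population: B_Ki67neg, scope: F, denominator: B}
  - {population: B_Ki67pos, scope: F, denominator: B}
  - {population: B_pH2Ax_Volhi, scope: GC, denominator: B}
  - {population: PC, scope: EF}
  - {population: PC, scope: F}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
  tzone_marker: CD4
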