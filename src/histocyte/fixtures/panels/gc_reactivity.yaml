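# Germinal-center reactivity panel: B cells (CD20/Bcl-6/Ki67), Tfh
# (CD4/PD-1/CD57/Bcl-6) and Tfr (CD4/FoxP3) in follicular topologies.
name: gc_reactivity
channels:
  - {name: DNA,   localization: nuclear}
  - {name: Ki67,  localization: nuclear}
  - {name: PD1,   localization: surface}
  - {name: CD20,  localization: surface}
  - {name: CD57,  localization: surface}
  - {name: Bcl6,  localization: nuclear}
  - {name: FoxP3, localization: nuclear}
  - {name: CD4,   localization: surface}
# sequential excitation groups of two; spillover only within a group
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [PD1, CD20, 0.09]
  - [CD20, PD1, 0.04]
  - [CD57, Bcl6, 0.08]
  - [Bcl6, CD57, 0.05]
  - [FoxP3, CD4, 0.08]
  - [CD4, FoxP3, 0.03]
thresholds:
  CD20:  {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67:  {method: gmm_edge, levels: 3}
  CD4:   {method: gmm_edge, levels: 2, n_components: 3}
  PD1:   {method: gmm_edge, levels: 3}
  Bcl6:  {method: gmm_edge, levels: 2}
  CD57:  {method: gmm_edge, levels: 2, n_components: 3}
  FoxP3: {method: gmm_edge, levels: 2, n_components: 3}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: B_Ki67neg, parent: B, terms: [[Ki67, "-"]]}
  - {name: B_Ki67pos, parent: B, terms: [[Ki67, "+"]]}
  - {name: B_Ki67pos_Bcl6hi, parent: B_Ki67pos, terms: [[Bcl6, "+"]]}
  - {name: B_Ki67pos_Bcl6lo, parent: B_Ki67pos, terms: [[Bcl6, "-"]]}
  - {name: CD4, parent: all, terms: [[CD4, "+"]]}
  - {name: Tfh, parent: CD4, terms: [[PD1, hi]]}
  - {name: Tfh_CD57pos, parent: Tfh, terms: [[CD57, "+"]]}
  - {name: Tfh_CD57neg, parent: Tfh, terms: [[CD57, "-"]]}
  - {name: Tfh_Bcl6hi, parent: Tfh, terms: [[Bcl6, "+"]]}
  - {name: Tfr, parent: CD4, terms: [[FoxP3, "+"]]}
quantification:
  - {population: B, scope: GC}
  - {population: CD4, scope: GC}
  - {population: Tfh, scope: GC}
  - {population: Tfh, scope: F, denominator: CD4}
  - {population: Tfh, scope: GC, denominator: CD4}
  - {population: Tfr, scope: F, denominator: CD4}
  - {population: B, scope: F}
  - {population: Tfh_CD57neg, scope: F, denominator: Tfh}
  - {population: Tfr, scope: F, per_follicle: true}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
  tzone_marker: CD4
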