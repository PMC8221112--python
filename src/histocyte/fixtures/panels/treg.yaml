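# T-cell regulation panel: Tregs/Tfrs by CD25, FoxP3, Helios and IL-10
# co-expression within CD4+ events, against the CD20/Ki67 tissue scaffold.
name: treg
channels:
  - {name: DNA,    localization: nuclear}
  - {name: Ki67,   localization: nuclear}
  - {name: Helios, localization: nuclear}
  - {name: CD25,   localization: surface}
  - {name: IL10,   localization: surface}
  - {name: CD20,   localization: surface}
  - {name: FoxP3,  localization: nuclear}
  - {name: CD4,    localization: surface}
spillover_pairs:
  - [DNA, Ki67, 0.10]
  - [Ki67, DNA, 0.05]
  - [Helios, CD25, 0.08]
  - [CD25, Helios, 0.04]
  - [IL10, CD20, 0.07]
  - [CD20, IL10, 0.05]
  - [FoxP3, CD4, 0.08]
  - [CD4, FoxP3, 0.03]
thresholds:
  CD20:   {method: gmm_edge, levels: 3, n_components: 4, k_sigma: 1.6}
  Ki67:   {method: gmm_edge, levels: 3}
  CD4:    {method: gmm_edge, levels: 2, n_components: 3}
  CD25:   {method: gmm_edge, levels: 2, n_components: 3}
  FoxP3:  {method: gmm_edge, levels: 2, n_components: 3}
  Helios: {method: gmm_edge, levels: 2, n_components: 3}
  IL10:   {method: gmm_edge, levels: 2, n_components: 3}
gates:
  - {name: B, parent: all, terms: [[CD20, hi/dim]]}
  - {name: CD4, parent: all, terms: [[CD4, "+"]]}
  - {name: Treg, parent: CD4, terms: [[CD25, "+"], [FoxP3, "+"]]}
  - {name: Tfr, parent: CD4, terms: [[CD25, hi], [FoxP3, "+"]]}
  - {name: Tfr_Helios, parent: Tfr, terms: [[Helios, "+"]]}
  - {name: Tfr_IL10hi, parent: Tfr, terms: [[IL10, hi]]}
  - {name: CD25hiHelios_FoxP3neg, parent: CD4, terms: [[CD25, hi], [Helios, "+"], [FoxP3, "-"]]}
quantification:
  - {population: Tfr, scope: F}
  - {population: Treg, scope: TZ, denominator: CD4}
  - {population: Tfr_IL10hi, scope: EF, denominator: CD4}
  - {population: Treg, scope: EF, denominator: CD4}
  - {population: Tfr, scope: F, per_follicle: true}
compartment:
  markers: {cd20: CD20, ki67: Ki67}
  tzone_marker: CD4
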