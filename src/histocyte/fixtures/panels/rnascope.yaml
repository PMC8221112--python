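# Multispectral RNAscope panel: HIV vRNA puncta with CD3/CD4 T-cell subsets
# and the FDC meshwork.  Follicles are CD3/CD4-poor islands in a T-cell-rich
# paracortex, so follicle detection runs on inverted CD3 density; without a
# proliferation marker the follicle is not subdivided (MZ stands for the
# whole follicle).
name: rnascope
channels:
  - {name: DNA,  localization: nuclear}
  - {name: CD3,  localization: surface}
  - {name: CD4,  localization: surface}
  - {name: FDC,  localization: surface}
  - {name: vRNA, localization: surface}
spillover_pairs:
  - [DNA, CD3, 0.08]
  - [CD3, DNA, 0.04]
  - [CD4, FDC, 0.07]
  - [FDC, CD4, 0.04]
  - [vRNA, CD4, 0.03]
thresholds:
  CD3: {method: gmm_edge, levels: 2, n_components: 3}
  CD4: {method: gmm_edge, levels: 3}
gates:
  - {name: T, parent: all, terms: [[CD3, "+"]]}
  - {name: T_CD4hi, parent: T, terms: [[CD4, hi]]}
  - {name: T_CD4dim, parent: T, terms: [[CD4, dim]]}
quantification:
  - {population: T, scope: EF}
  - {population: T_CD4hi, scope: EF, denominator: T}
compartment:
  markers: {cd20: CD3}
  polarity: low
structural_markers: {fdc: FDC}
rnascope:
  vrna_channel: vRNA
  t_gate: T
  cd4hi_gate: T_CD4hi
  cd4dim_gate: T_CD4dim
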