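# Evolutionary phases of the protein world, defined by which Venn groups
# (superkingdom/virus sharing patterns) have emerged.  Windows are node-distance
# (nd) intervals; right-open except the last.  Boundaries between the published
# worked examples are interpolated and editable.
phases:
  - label: "Phase 0 (nulla)"
    nd_min: 0.0
    nd_max: 0.045
    venn_groups: [ABEV]
  - label: "Phase I (rise of viral ancestors)"
    nd_min: 0.045
    nd_max: 0.19
    venn_groups: [ABEV, ABE]
  - label: "Phase II (birth of archaeal ancestors)"
    nd_min: 0.19
    nd_max: 0.455
    venn_groups: [ABEV, ABE, BEV, BE]
  - label: "Phase III (diversification of Bacteria)"
    nd_min: 0.455
    nd_max: 0.47
    venn_groups: [ABEV, ABE, BEV, BE, AB, AE, EV, BV]
  - label: "Phase IV (organismal diversification)"
    nd_min: 0.47
    nd_max: 0.9
    venn_groups: [ABEV, ABE, BEV, BE, AB, AE, EV, BV, AV, AEV, ABV]
  - label: "Phase V (superkingdom specification)"
    nd_min: 0.9
    nd_max: 1.0
    venn_groups: [ABEV, ABE, BEV, BE, AB, AE, EV, BV, AV, AEV, ABV, A, B, E, V]
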