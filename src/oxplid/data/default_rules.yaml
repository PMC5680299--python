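# Default oxidation rule set.
#
# CALIBRATION NOTE.  The exact membership of the three oxidation levels is a
# curated property of this configuration, anchored to two worked enumeration
# counts for the default level (2): oxidation of PC(18:2/18:2) must yield 17
# distinct products after merging positional isomers, and PC(16:0/20:4) at
# least 104.  The choices that reproduce those anchors are:
#   * at most one modification per double-bond unit;
#   * an oxygen-addition budget of max_oxygens atoms per residue
#     (a hydroperoxide spends 2);
#   * chain cleavage at each double-bond position, producing both an
#     aldehyde- and a carboxyl-terminated truncated chain;
#   * secondary oxygen addition on a truncated chain only when at least
#     decoration_min_residual double bonds remain (a lone residual double
#     bond has no bis-allylic methylene to abstract from);
#   * one ring product per prostane template and per three-double-bond
#     window, positional isomers retained.
# Editing any of these moves the enumeration counts.

oap_transforms:
  # pattern/replacement are illustrative SMILES segments for one double-bond
  # unit (C=C plus a neighboring (bis-)allylic carbon); the engine works on
  # the declared type and formula delta, which must stay consistent.
  - {name: hydroxy-allylic,        type: OH,    target: allylic,     pattern: "C=CC",  replacement: "C=CC(O)",  delta: {O: 1, H: 0}}
  - {name: hydroxy-bis-allylic,    type: OH,    target: bis-allylic, pattern: "C=CCC=C", replacement: "C=CC(O)C=C", delta: {O: 1, H: 0}}
  - {name: hydroperoxy-allylic,    type: OOH,   target: allylic,     pattern: "C=CC",  replacement: "C=CC(OO)", delta: {O: 2, H: 0}}
  - {name: hydroperoxy-bis-allylic, type: OOH,  target: bis-allylic, pattern: "C=CCC=C", replacement: "C=CC(OO)C=C", delta: {O: 2, H: 0}}
  - {name: keto-allylic,           type: KETO,  target: allylic,     pattern: "C=CC",  replacement: "C=CC(=O)", delta: {O: 1, H: -2}}
  - {name: keto-bis-allylic,       type: KETO,  target: bis-allylic, pattern: "C=CCC=C", replacement: "C=CC(=O)C=C", delta: {O: 1, H: -2}}
  - {name: epoxy-double-bond,      type: EPOXY, target: double-bond, pattern: "C=C",   replacement: "C1OC1",    delta: {O: 1, H: 0}}
  - {name: epoxy-conjugated,       type: EPOXY, target: double-bond, pattern: "C=CC=C", replacement: "C1OC1C=C", delta: {O: 1, H: 0}}

ocp_transforms:
  # Hock-type cleavage at a double-bond position; "shifted" cuts one carbon
  # closer to the carboxyl end and is reserved for level 3.
  - {name: aldehyde-at-bond,  terminal: CHO,  shifted: false, delta: {O: 1, H: -2}}
  - {name: carboxyl-at-bond,  terminal: COOH, shifted: false, delta: {O: 2, H: -2}}
  - {name: aldehyde-shifted,  terminal: CHO,  shifted: true,  delta: {O: 1, H: -2}}
  - {name: carboxyl-shifted,  terminal: COOH, shifted: true,  delta: {O: 2, H: -2}}

prostane_templates:
  - {ring: A, experimental: false}
  - {ring: D, experimental: false}
  - {ring: E, experimental: false}
  - {ring: F, experimental: false}
  - {ring: H, experimental: false}
  # thromboxane/levuglandin-like cores are not shipped as defaults

levels:
  1:  # most common mild oxidation
    oap_types: [KETO, OH]
    max_total_mods: 2
    max_oxygens: 2
    ocp_terminals: [CHO, COOH]
    shifted_cleavage: false
    ocp_decoration: true
    decoration_min_residual: 2
    prostane_rings: []
  2:  # pathway dependent (default)
    oap_types: [KETO, OH, OOH, EPOXY]
    max_total_mods: 3
    max_oxygens: 3
    ocp_terminals: [CHO, COOH]
    shifted_cleavage: false
    ocp_decoration: true
    decoration_min_residual: 2
    prostane_rings: [A, D, E, F, H]
  3:  # less often reported oxidation routes
    oap_types: [KETO, OH, OOH, EPOXY]
    max_total_mods: 4
    max_oxygens: 4
    ocp_terminals: [CHO, COOH]
    shifted_cleavage: true
    ocp_decoration: true
    decoration_min_residual: 2
    prostane_rings: [A, D, E, F, H]

default_level: 2
include_lyso: false
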