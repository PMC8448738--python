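# Role-mapping patterns for cyanobacterial phycobilisome depositions.
#
# These rules assign subunit roles from mmCIF entity descriptions
# (_entity.pdbx_description), matched case-insensitively against the
# standard UniProt-style protein names used in PBS depositions.  Region
# labels (cylinder, trimer layer, rod name) are NOT encoded in coordinate
# files and cannot be assigned by pattern; they must be derived once per
# deposition by inspecting the model and recorded in a per-entry config.
# Compartment membership is still recoverable role-wise: Apc* subunits sit
# in the core, Cpc* subunits in the rods, which is what the core/rod
# censuses rely on when no per-chain region config is given.
patterns:
  - {match: "allophycocyanin[- ]?b|apcd|alpha-?b", field: description, role: ApcD}
  - {match: "core[- ]membrane linker|apce", field: description, role: ApcE}
  - {match: "apcf|beta[- ]?18|b18", field: description, role: ApcF}
  - {match: "allophycocyanin.*alpha|apca", field: description, role: ApcA}
  - {match: "allophycocyanin.*beta|apcb", field: description, role: ApcB}
  - {match: "rod[- ]core linker|cpcg", field: description, role: CpcG}
  - {match: "rod linker|cpcc", field: description, role: CpcC}
  - {match: "core linker|apcc|7\\.8 ?kda", field: description, role: ApcC}
  - {match: "phycocyanin.*alpha|cpca", field: description, role: CpcA}
  - {match: "phycocyanin.*beta|cpcb", field: description, role: CpcB}
chains: {}
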