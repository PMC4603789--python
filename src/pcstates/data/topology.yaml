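# Default progression graph between living clinical states.
# Edges to DEAD are implicit (every living state can die) and added by
# the loader. Disease only progresses: the graph is acyclic.
#
# Routing fractions split each state's progression outflow among its
# living successors and sum to 1 per source.
#   - LOCALLY_ADVANCED: the split equals the weight share of hormonal
#     arms in the survival table (hormonal-arm failures are castrate →
#     NMCRPC; the rest relapse non-castrate). 0.5 matches the shipped
#     uniform arm weights and is recomputed when weights change.
#   - NMCRPC and METASTATIC_NONCASTRATE split between asymptomatic and
#     symptomatic mCRPC. The source model based this split on an
#     external chemotherapy-sequencing cohort without printing the
#     number; 0.50/0.50 is an explicit placeholder assumption.
edges:
  - [LOCALIZED, RISING_PSA_NONCASTRATE]
  - [LOCALLY_ADVANCED, RISING_PSA_NONCASTRATE]
  - [LOCALLY_ADVANCED, NMCRPC]
  - [RISING_PSA_NONCASTRATE, NMCRPC]
  - [NMCRPC, MCRPC_ASYMPTOMATIC]
  - [NMCRPC, MCRPC_SYMPTOMATIC]
  - [METASTATIC_NONCASTRATE, MCRPC_ASYMPTOMATIC]
  - [METASTATIC_NONCASTRATE, MCRPC_SYMPTOMATIC]
  - [MCRPC_ASYMPTOMATIC, MCRPC_SYMPTOMATIC]
  - [MCRPC_SYMPTOMATIC, MCRPC_POSTCHEMO]
routing:
  LOCALIZED:
    RISING_PSA_NONCASTRATE: 1.0
  LOCALLY_ADVANCED:
    RISING_PSA_NONCASTRATE: 0.5
    NMCRPC: 0.5
  RISING_PSA_NONCASTRATE:
    NMCRPC: 1.0
  NMCRPC:
    MCRPC_ASYMPTOMATIC: 0.5
    MCRPC_SYMPTOMATIC: 0.5
  METASTATIC_NONCASTRATE:
    MCRPC_ASYMPTOMATIC: 0.5
    MCRPC_SYMPTOMATIC: 0.5
  MCRPC_ASYMPTOMATIC:
    MCRPC_SYMPTOMATIC: 1.0
  MCRPC_SYMPTOMATIC:
    MCRPC_POSTCHEMO: 1.0
  MCRPC_POSTCHEMO: {}
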