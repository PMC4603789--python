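# The three hypothetical intervention scenarios: a novel therapy
# introduced in 2015 that improves PFS in nmCRPC, OS in the mCRPC
# states, or both. Improvements are relative gains (0.25 = 25%).
# `combined` composes the two single-state interventions (PFS gain in
# nmCRPC and OS gain in mCRPC applied simultaneously).
scenarios:
  nmcrpc:
    - name: nmcrpc_pfs
      states: [NMCRPC]
      pfs_improvement: 0.25
      os_improvement: 0.0
      introduction_year: 2015
  mcrpc:
    - name: mcrpc_os
      states: [MCRPC_ASYMPTOMATIC, MCRPC_SYMPTOMATIC, MCRPC_POSTCHEMO]
      pfs_improvement: 0.0
      os_improvement: 0.25
      introduction_year: 2015
  combined:
    - name: nmcrpc_pfs
      states: [NMCRPC]
      pfs_improvement: 0.25
      os_improvement: 0.0
      introduction_year: 2015
    - name: mcrpc_os
      states: [MCRPC_ASYMPTOMATIC, MCRPC_SYMPTOMATIC, MCRPC_POSTCHEMO]
      pfs_improvement: 0.0
      os_improvement: 0.25
      introduction_year: 2015
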