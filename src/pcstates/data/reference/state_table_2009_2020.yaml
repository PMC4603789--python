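# Published per-state incidence / prevalence / mortality of the
# base-case model (2009) and its 2020 projection, transcribed exactly
# as printed. `source` tags the table cell of origin.
#
# NOTE (transcribed faithfully, not corrected): the printed 2020
# localized-state mortality (10,915) is inconsistent with the printed
# 2020 all-state mortality total of 219,360 quoted in the text — the
# eight 2020 mortality cells sum to 122,360. The cell is shipped as
# printed; see the methods note for discussion.
table:
  2009:
    LOCALIZED:              {incidence: 194765, prevalence: 1383920, mortality: 73485, source: "state table, base-case 2009, localized row"}
    LOCALLY_ADVANCED:       {incidence: 27555,  prevalence: 199410,  mortality: 12845, source: "state table, base-case 2009, locally advanced row"}
    RISING_PSA_NONCASTRATE: {incidence: 83260,  prevalence: 446540,  mortality: 26510, source: "state table, base-case 2009, biochemical failure after local therapy row"}
    NMCRPC:                 {incidence: 49390,  prevalence: 91780,   mortality: 15130, source: "state table, base-case 2009, biochemical failure after hormonal therapy row"}
    METASTATIC_NONCASTRATE: {incidence: 9790,   prevalence: 35520,   mortality: 5795,  source: "state table, base-case 2009, newly diagnosed metastatic row"}
    MCRPC_ASYMPTOMATIC:     {incidence: 17185,  prevalence: 6745,    mortality: 2205,  source: "state table, base-case 2009, asymptomatic mCRPC row"}
    MCRPC_SYMPTOMATIC:      {incidence: 30010,  prevalence: 32145,   mortality: 15415, source: "state table, base-case 2009, symptomatic mCRPC row"}
    MCRPC_POSTCHEMO:        {incidence: 17580,  prevalence: 23220,   mortality: 16905, source: "state table, base-case 2009, post-chemotherapy mCRPC row"}
  2020:
    LOCALIZED:              {incidence: 259715, prevalence: 2075945, mortality: 10915, source: "state table, 2020 projection, localized row (mortality cell printed as-is; see header note)"}
    LOCALLY_ADVANCED:       {incidence: 37310,  prevalence: 237515,  mortality: 13920, source: "state table, 2020 projection, locally advanced row"}
    RISING_PSA_NONCASTRATE: {incidence: 98800,  prevalence: 528770,  mortality: 29725, source: "state table, 2020 projection, biochemical failure after local therapy row"}
    NMCRPC:                 {incidence: 58960,  prevalence: 112065,  mortality: 18615, source: "state table, 2020 projection, biochemical failure after hormonal therapy row"}
    METASTATIC_NONCASTRATE: {incidence: 13575,  prevalence: 41495,   mortality: 6565,  source: "state table, 2020 projection, newly diagnosed metastatic row"}
    MCRPC_ASYMPTOMATIC:     {incidence: 20255,  prevalence: 8320,    mortality: 2785,  source: "state table, 2020 projection, asymptomatic mCRPC row"}
    MCRPC_SYMPTOMATIC:      {incidence: 36640,  prevalence: 39650,   mortality: 18600, source: "state table, 2020 projection, symptomatic mCRPC row"}
    MCRPC_POSTCHEMO:        {incidence: 21700,  prevalence: 28720,   mortality: 21235, source: "state table, 2020 projection, post-chemotherapy mCRPC row"}
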