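# Published scenario outcomes (novel therapy introduced 2015):
# aggregate mCRPC incidence / prevalence / mortality and nmCRPC
# prevalence in 2017 and 2020 under the baseline and the three
# intervention scenarios, transcribed exactly as printed. `null`
# transcribes the table's "NA" cells (metrics the scenario cannot
# change: an OS-only mCRPC intervention leaves mCRPC entry incidence
# and nmCRPC prevalence untouched).
table:
  2017:
    mcrpc_incidence:  {baseline: 41721, mcrpc: null,  nmcrpc: 37131, combined: 37708, source: "scenario table, 2017 block, mCRPC incidence row"}
    mcrpc_prevalence: {baseline: 72677, mcrpc: 75132, nmcrpc: 68837, combined: 72115, source: "scenario table, 2017 block, mCRPC prevalence row"}
    mcrpc_mortality:  {baseline: 39870, mcrpc: 36657, nmcrpc: 38156, combined: 34926, source: "scenario table, 2017 block, mCRPC mortality row"}
    nmcrpc_prevalence: {baseline: 107124, mcrpc: null, nmcrpc: 109540, combined: 110954, source: "scenario table, 2017 block, nmCRPC row"}
  2020:
    mcrpc_incidence:  {baseline: 43211, mcrpc: null,  nmcrpc: 38150, combined: 39327, source: "scenario table, 2020 block, mCRPC incidence row"}
    mcrpc_prevalence: {baseline: 76431, mcrpc: 89879, nmcrpc: 67796, combined: 80894, source: "scenario table, 2020 block, mCRPC prevalence row"}
    mcrpc_mortality:  {baseline: 41833, mcrpc: 39801, nmcrpc: 38139, combined: 35370, source: "scenario table, 2020 block, mCRPC mortality row"}
    nmcrpc_prevalence: {baseline: 112410, mcrpc: null, nmcrpc: 126332, combined: 126744, source: "scenario table, 2020 block, nmCRPC row"}
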