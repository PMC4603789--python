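# Anchors for the default diagnosed-incidence series (persons/year by
# stage at diagnosis).
#
# The model's original 1990-2008 series came from SEER age-specific
# rates and is not published; this default is NON-AUTHORITATIVE. It
# linearly interpolates each stage from a chosen 1990 level to the
# published 2009 state-table values, then grows geometrically so the
# 2020 projection hits the published 2020 values exactly.
#
# 1990 level: 170,000 total diagnoses with the 2009 stage split
# (~84% localized / 12% locally advanced / 4% metastatic), a realistic
# early-PSA-era order of magnitude.
anchors:
  1990:
    localized: 142800
    locally_advanced: 20400
    metastatic: 6800
  2009:
    localized: 194765
    locally_advanced: 27555
    metastatic: 9790
projection:
  base_year: 2009
  anchors:
    localized: [2020, 259715]
    locally_advanced: [2020, 37310]
    metastatic: [2020, 13575]
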