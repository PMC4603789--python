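# Landmark survival inputs per clinical state, by treatment arm.
# os5/os10: overall-survival fraction at 5/10 years from state entry;
# pfs5/pfs10: progression-free-survival fraction at the same landmarks.
# Values transcribed from the published data-source table of the model
# (pivotal phase-III trials, meta-analyses and observational cohorts,
# one row per treatment approach).
#
# `weight` is the share of the state's population on that arm. The
# original model used (unpublished) SEER treatment-mix weights; the
# uniform weights below are explicit placeholders.
# `hormonal` marks arms whose regimen includes hormonal therapy; it
# drives the default routing of locally-advanced progressors (hormonal
# arms fail into castrate biochemical relapse, the rest into
# non-castrate rising PSA).
states:
  LOCALIZED:
    arms:
      - label: watchful_waiting
        source: Bill-Axelson 2008
        weight: 0.25
        hormonal: false
        os5: 0.910
        os10: 0.690
        pfs5: 0.730
        pfs10: 0.585
      - label: surgery_only
        source: Moreira 2009
        weight: 0.25
        hormonal: false
        os5: 0.920
        os10: 0.800
        pfs5: 0.780
        pfs10: 0.720
      - label: radiation_only
        source: D'Amico 2006
        weight: 0.25
        hormonal: false
        os5: 0.890
        os10: 0.600
        pfs5: 0.260
        pfs10: 0.070
      - label: hormonal_only
        source: Antonarakis 2007
        weight: 0.25
        hormonal: true
        os5: 0.704
        os10: 0.487
        pfs5: 0.565
        pfs10: 0.318
  LOCALLY_ADVANCED:
    arms:
      - label: watchful_waiting
        source: Shappley 2009
        weight: 0.16666666666666666
        hormonal: false
        os5: 0.636
        os10: 0.354
        pfs5: 0.510
        pfs10: 0.300
      - label: surgery_plus_hormonal
        source: Antonarakis 2007
        weight: 0.16666666666666666
        hormonal: true
        os5: 0.888
        os10: 0.791
        pfs5: 0.649
        pfs10: 0.415
      - label: surgery_plus_radiation
        source: Bolla 2005
        weight: 0.16666666666666666
        hormonal: false
        os5: 0.908
        os10: 0.821
        pfs5: 0.745
        pfs10: 0.565
      - label: radiation_only
        source: Bolla 2002
        weight: 0.16666666666666666
        hormonal: false
        os5: 0.799
        os10: 0.559
        pfs5: 0.452
        pfs10: 0.093
      - label: radiation_plus_hormonal
        source: Antonarakis 2007
        weight: 0.16666666666666666
        hormonal: true
        os5: 0.824
        os10: 0.684
        pfs5: 0.525
        pfs10: 0.276
      - label: hormonal_only
        source: Antonarakis 2007
        weight: 0.16666666666666669
        hormonal: true
        os5: 0.704
        os10: 0.487
        pfs5: 0.565
        pfs10: 0.318
  RISING_PSA_NONCASTRATE:
    arms:
      - label: natural_history
        source: Antonarakis 2011
        weight: 1.0
        hormonal: false
        os5: 0.882
        os10: 0.778
        pfs5: 0.315
        pfs10: 0.099
  NMCRPC:
    arms:
      - label: natural_history
        source: Smith 2011
        weight: 1.0
        hormonal: true
        os5: 0.350
        os10: 0.002
        pfs5: 0.220
        pfs10: 0.081
  METASTATIC_NONCASTRATE:
    # OS and PFS for this state come from different cohorts (OS from a
    # hormone-therapy trial population, PFS from an observational
    # series); they are combined into one arm.
    arms:
      - label: any_treatment
        source: Tangen 2012 (OS) / Noguchi 2004 (PFS)
        weight: 1.0
        hormonal: true
        os5: 0.430
        os10: 0.180
        pfs5: 0.238
        pfs10: 0.076
  MCRPC_ASYMPTOMATIC:
    arms:
      - label: immunotherapy
        source: Small 2006
        weight: 1.0
        hormonal: false
        os5: 0.106
        os10: 0.023
        pfs5: 0.000
        pfs10: 0.000
  MCRPC_SYMPTOMATIC:
    arms:
      - label: chemotherapy
        source: Petrylak 2004
        weight: 1.0
        hormonal: false
        os5: 0.054
        os10: 0.003
        pfs5: 0.000
        pfs10: 0.000
  MCRPC_POSTCHEMO:
    arms:
      - label: natural_history
        source: de Bono 2011
        weight: 1.0
        hormonal: false
        os5: 0.016
        os10: 0.000
        pfs5: 0.000
        pfs10: 0.000
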