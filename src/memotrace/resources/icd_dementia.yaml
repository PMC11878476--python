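# Dementia phenotyping code set (prefix match on ICD-9/ICD-10 codes).
#
# The study's own appendix of phenotyping codes is not redistributable,
# so this default ships the standard dementia code families used in EHR
# phenotyping; sites should review and extend it locally.
icd_prefixes:
  # ICD-10
  - F00
  - F01
  - F02
  - F03
  - F05.1
  - G30
  - G31.0
  - G31.83
  # ICD-9
  - "290"
  - "294.1"
  - "331.0"
min_distinct_code_dates: 3
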