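# Default signature subset for refitting colorectal tumor catalogues:
# 15 single-base-substitution and 5 indel signatures reported in CRC
# tissue.  The subset is configuration, not code — edit to match the
# reference signature matrix in use.  SBS3 and ID6 must be present for
# the HRD rule to be evaluable.
sbs:
  - SBS1
  - SBS3
  - SBS5
  - SBS10a
  - SBS10b
  - SBS15
  - SBS17a
  - SBS17b
  - SBS18
  - SBS28
  - SBS30
  - SBS37
  - SBS40
  - SBS44
  - SBS88
id:
  - ID1
  - ID2
  - ID4
  - ID5
  - ID6
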