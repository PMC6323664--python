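# UICC/AJCC 8th-edition pathological stage grouping for gastric cancer,
# restricted to the cells reachable by M0 disease with N3 nodal
# involvement (>= 7 metastatic lymph nodes).  The modified system reuses
# this grouping with the N3a/N3b boundary moved from 15 to the scan's
# selected cutoff.
# resource version: ajcc8-n3m0-v1
name: eighth
n3a_n3b_cutoff: 15
stage_order: [IIB, IIIA, IIIB, IIIC]
grouping:
  T1:  {N3a: IIB,  N3b: IIIB}
  T2:  {N3a: IIIA, N3b: IIIB}
  T3:  {N3a: IIIB, N3b: IIIC}
  T4a: {N3a: IIIB, N3b: IIIC}
  T4b: {N3a: IIIC, N3b: IIIC}
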