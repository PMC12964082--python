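study_id,rxr_r,rxr_l,mix_r,mix_l,lxl_r,lxl_l,pairs_rxr,pairs_mix,pairs_lxl,m_p
study01,992,235,220,104,5,4,409,108,3,0.10961538461538461
study02,709,65,110,34,11,1,258,48,4,0.09032258064516129
study03,2478,246,1180,242,143,61,908,474,68,0.2103448275862069
study04,513,36,136,29,6,0,183,55,2,0.12291666666666666
study05,1645,128,373,98,24,12,591,157,12,0.11907894736842105
study06,711,219,141,87,6,6,310,76,4,0.1076923076923077
study07,1661,565,757,293,64,50,742,350,38,0.18849557522123894
study08,629,52,110,34,8,7,227,48,5,0.10357142857142858
study09,1448,124,317,67,14,10,524,128,8,0.10909090909090909
study10,674,61,406,77,58,14,245,161,24,0.24302325581395348
study11,2032,353,380,151,15,9,795,177,8,0.09846938775510204
study12,555,156,229,83,21,6,237,104,9,0.1742857142857143
study13,1192,194,271,92,12,9,462,121,7,0.11440677966101695
study14,467,46,225,42,19,11,171,89,10,0.20185185185185187
study15,1294,116,751,134,137,28,470,295,55,0.24695121951219512
study16,789,222,240,108,10,11,337,116,7,0.14130434782608695
study17,769,68,174,57,8,4,279,77,4,0.11805555555555555
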