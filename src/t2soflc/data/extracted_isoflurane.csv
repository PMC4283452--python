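output_var,in1_var,in1_label,in2_var,in2_label,consequent_label
isoflurane,E_MR,NS,IE_MR,NS,ZE
isoflurane,E_MR,NS,IE_MR,ZE,ZE
isoflurane,E_MR,NS,IE_MR,PB,ZE
isoflurane,E_MR,ZE,IE_MR,ZE,PS
isoflurane,E_MR,ZE,IE_MR,PM,ZE
isoflurane,E_MR,NS,E_BP,NS,PS
isoflurane,E_MR,NS,E_BP,ZE,ZE
isoflurane,E_MR,NS,E_BP,PS,ZE
isoflurane,E_MR,NS,E_BP,PB,ZE
isoflurane,E_MR,ZE,E_BP,ZE,ZE
isoflurane,E_MR,ZE,E_BP,PM,ZE
isoflurane,E_MR,NS,IE_BP,NS,ZE
isoflurane,E_MR,ZE,IE_BP,ZE,PS
isoflurane,IE_MR,NS,E_BP,NS,ZE
isoflurane,IE_MR,NS,E_BP,PS,ZE
isoflurane,IE_MR,NS,E_BP,PB,PS
isoflurane,IE_MR,ZE,E_BP,NS,PS
isoflurane,IE_MR,ZE,E_BP,ZE,PS
isoflurane,IE_MR,ZE,E_BP,PM,PS
isoflurane,IE_MR,ZE,E_BP,PB,PS
isoflurane,IE_MR,PS,E_BP,NS,PS
isoflurane,IE_MR,PS,E_BP,ZE,PS
isoflurane,IE_MR,PM,E_BP,NS,PS
isoflurane,IE_MR,PM,E_BP,ZE,PS
isoflurane,IE_MR,PB,E_BP,NS,PM
isoflurane,IE_MR,PB,E_BP,ZE,PS
isoflurane,IE_MR,NS,IE_BP,NS,ZE
isoflurane,IE_MR,ZE,IE_BP,NS,PS
isoflurane,IE_MR,ZE,IE_BP,ZE,PS
isoflurane,IE_MR,PS,IE_BP,NS,PS
isoflurane,IE_MR,PM,IE_BP,ZE,PS
isoflurane,IE_MR,PB,IE_BP,NS,PM
isoflurane,E_BP,NS,IE_BP,NS,ZE
isoflurane,E_BP,ZE,IE_BP,NS,PS
isoflurane,E_BP,ZE,IE_BP,ZE,PS
isoflurane,E_BP,PM,IE_BP,ZE,PM
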