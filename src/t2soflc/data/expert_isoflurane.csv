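output_var,in1_var,in1_label,in2_var,in2_label,consequent_label
isoflurane,E_MR,NB,IE_MR,NB,ZE
isoflurane,E_MR,NB,IE_MR,NS,ZE
isoflurane,E_MR,NB,IE_MR,PS,ZE
isoflurane,E_MR,NB,IE_MR,PB,ZE
isoflurane,E_MR,NM,IE_MR,NM,ZE
isoflurane,E_MR,NM,IE_MR,ZE,ZE
isoflurane,E_MR,NM,IE_MR,PM,ZE
isoflurane,E_MR,NS,IE_MR,NB,ZE
isoflurane,E_MR,NS,IE_MR,NS,ZE
isoflurane,E_MR,NS,IE_MR,PS,ZE
isoflurane,E_MR,NS,IE_MR,PB,ZE
isoflurane,E_MR,ZE,IE_MR,NM,ZE
isoflurane,E_MR,ZE,IE_MR,ZE,ZE
isoflurane,E_MR,ZE,IE_MR,PM,ZE
isoflurane,E_MR,PS,IE_MR,NB,PM
isoflurane,E_MR,PS,IE_MR,NS,PS
isoflurane,E_MR,PS,IE_MR,PS,PS
isoflurane,E_MR,PS,IE_MR,PB,ZE
isoflurane,E_MR,PM,IE_MR,NM,PM
isoflurane,E_MR,PM,IE_MR,ZE,PS
isoflurane,E_MR,PM,IE_MR,PM,ZE
isoflurane,E_MR,PB,IE_MR,NB,PB
isoflurane,E_MR,PB,IE_MR,NS,PM
isoflurane,E_MR,PB,IE_MR,PS,PS
isoflurane,E_MR,PB,IE_MR,PB,PS
isoflurane,E_MR,NB,E_BP,NB,PB
isoflurane,E_MR,NB,E_BP,NS,PM
isoflurane,E_MR,NB,E_BP,PS,ZE
isoflurane,E_MR,NB,E_BP,PB,ZE
isoflurane,E_MR,NM,E_BP,NM,PM
isoflurane,E_MR,NM,E_BP,ZE,ZE
isoflurane,E_MR,NM,E_BP,PM,ZE
isoflurane,E_MR,NS,E_BP,NB,PS
isoflurane,E_MR,NS,E_BP,NS,PS
isoflurane,E_MR,NS,E_BP,PS,ZE
isoflurane,E_MR,NS,E_BP,PB,ZE
isoflurane,E_MR,ZE,E_BP,NM,ZE
isoflurane,E_MR,ZE,E_BP,ZE,ZE
isoflurane,E_MR,ZE,E_BP,PM,ZE
isoflurane,E_MR,PS,E_BP,NB,ZE
isoflurane,E_MR,PS,E_BP,NS,ZE
isoflurane,E_MR,PS,E_BP,PS,ZE
isoflurane,E_MR,PS,E_BP,PB,ZE
isoflurane,E_MR,PM,E_BP,NM,ZE
isoflurane,E_MR,PM,E_BP,ZE,ZE
isoflurane,E_MR,PM,E_BP,PM,ZE
isoflurane,E_MR,PB,E_BP,NB,ZE
isoflurane,E_MR,PB,E_BP,NS,ZE
isoflurane,E_MR,PB,E_BP,PS,ZE
isoflurane,E_MR,PB,E_BP,PB,ZE
isoflurane,E_MR,NB,IE_BP,NB,ZE
isoflurane,E_MR,NB,IE_BP,NS,ZE
isoflurane,E_MR,NB,IE_BP,PS,ZE
isoflurane,E_MR,NB,IE_BP,PB,ZE
isoflurane,E_MR,NM,IE_BP,NM,ZE
isoflurane,E_MR,NM,IE_BP,ZE,ZE
isoflurane,E_MR,NM,IE_BP,PM,ZE
isoflurane,E_MR,NS,IE_BP,NB,ZE
isoflurane,E_MR,NS,IE_BP,NS,ZE
isoflurane,E_MR,NS,IE_BP,PS,ZE
isoflurane,E_MR,NS,IE_BP,PB,ZE
isoflurane,E_MR,ZE,IE_BP,NM,ZE
isoflurane,E_MR,ZE,IE_BP,ZE,ZE
isoflurane,E_MR,ZE,IE_BP,PM,ZE
isoflurane,E_MR,PS,IE_BP,NB,PM
isoflurane,E_MR,PS,IE_BP,NS,PS
isoflurane,E_MR,PS,IE_BP,PS,ZE
isoflurane,E_MR,PS,IE_BP,PB,ZE
isoflurane,E_MR,PM,IE_BP,NM,PM
isoflurane,E_MR,PM,IE_BP,ZE,ZE
isoflurane,E_MR,PM,IE_BP,PM,ZE
isoflurane,E_MR,PB,IE_BP,NB,PB
isoflurane,E_MR,PB,IE_BP,NS,PM
isoflurane,E_MR,PB,IE_BP,PS,ZE
isoflurane,E_MR,PB,IE_BP,PB,ZE
isoflurane,IE_MR,NB,E_BP,NB,ZE
isoflurane,IE_MR,NB,E_BP,NS,ZE
isoflurane,IE_MR,NB,E_BP,PS,ZE
isoflurane,IE_MR,NB,E_BP,PB,ZE
isoflurane,IE_MR,NM,E_BP,NM,ZE
isoflurane,IE_MR,NM,E_BP,ZE,ZE
isoflurane,IE_MR,NM,E_BP,PM,ZE
isoflurane,IE_MR,NS,E_BP,NB,ZE
isoflurane,IE_MR,NS,E_BP,NS,ZE
isoflurane,IE_MR,NS,E_BP,PS,ZE
isoflurane,IE_MR,NS,E_BP,PB,ZE
isoflurane,IE_MR,ZE,E_BP,NM,ZE
isoflurane,IE_MR,ZE,E_BP,ZE,ZE
isoflurane,IE_MR,ZE,E_BP,PM,ZE
isoflurane,IE_MR,PS,E_BP,NB,PM
isoflurane,IE_MR,PS,E_BP,NS,PS
isoflurane,IE_MR,PS,E_BP,PS,PS
isoflurane,IE_MR,PS,E_BP,PB,ZE
isoflurane,IE_MR,PM,E_BP,NM,PM
isoflurane,IE_MR,PM,E_BP,ZE,PS
isoflurane,IE_MR,PM,E_BP,PM,ZE
isoflurane,IE_MR,PB,E_BP,NB,PB
isoflurane,IE_MR,PB,E_BP,NS,PM
isoflurane,IE_MR,PB,E_BP,PS,PS
isoflurane,IE_MR,PB,E_BP,PB,PS
isoflurane,IE_MR,NB,IE_BP,NB,ZE
isoflurane,IE_MR,NB,IE_BP,NS,ZE
isoflurane,IE_MR,NB,IE_BP,PS,ZE
isoflurane,IE_MR,NB,IE_BP,PB,ZE
isoflurane,IE_MR,NM,IE_BP,NM,ZE
isoflurane,IE_MR,NM,IE_BP,ZE,ZE
isoflurane,IE_MR,NM,IE_BP,PM,ZE
isoflurane,IE_MR,NS,IE_BP,NB,ZE
isoflurane,IE_MR,NS,IE_BP,NS,ZE
isoflurane,IE_MR,NS,IE_BP,PS,ZE
isoflurane,IE_MR,NS,IE_BP,PB,ZE
isoflurane,IE_MR,ZE,IE_BP,NM,ZE
isoflurane,IE_MR,ZE,IE_BP,ZE,ZE
isoflurane,IE_MR,ZE,IE_BP,PM,ZE
isoflurane,IE_MR,PS,IE_BP,NB,PM
isoflurane,IE_MR,PS,IE_BP,NS,PS
isoflurane,IE_MR,PS,IE_BP,PS,PS
isoflurane,IE_MR,PS,IE_BP,PB,ZE
isoflurane,IE_MR,PM,IE_BP,NM,PM
isoflurane,IE_MR,PM,IE_BP,ZE,PS
isoflurane,IE_MR,PM,IE_BP,PM,ZE
isoflurane,IE_MR,PB,IE_BP,NB,PB
isoflurane,IE_MR,PB,IE_BP,NS,PM
isoflurane,IE_MR,PB,IE_BP,PS,PS
isoflurane,IE_MR,PB,IE_BP,PB,PS
isoflurane,E_BP,NB,IE_BP,NB,ZE
isoflurane,E_BP,NB,IE_BP,NS,ZE
isoflurane,E_BP,NB,IE_BP,PS,ZE
isoflurane,E_BP,NB,IE_BP,PB,PS
isoflurane,E_BP,NM,IE_BP,NM,ZE
isoflurane,E_BP,NM,IE_BP,ZE,ZE
isoflurane,E_BP,NM,IE_BP,PM,PS
isoflurane,E_BP,NS,IE_BP,NB,ZE
isoflurane,E_BP,NS,IE_BP,NS,ZE
isoflurane,E_BP,NS,IE_BP,PS,PS
isoflurane,E_BP,NS,IE_BP,PB,PM
isoflurane,E_BP,ZE,IE_BP,NM,ZE
isoflurane,E_BP,ZE,IE_BP,ZE,ZE
isoflurane,E_BP,ZE,IE_BP,PM,PM
isoflurane,E_BP,PS,IE_BP,NB,ZE
isoflurane,E_BP,PS,IE_BP,NS,PS
isoflurane,E_BP,PS,IE_BP,PS,PS
isoflurane,E_BP,PS,IE_BP,PB,PB
isoflurane,E_BP,PM,IE_BP,NM,PS
isoflurane,E_BP,PM,IE_BP,ZE,PM
isoflurane,E_BP,PM,IE_BP,PM,PB
isoflurane,E_BP,PB,IE_BP,NB,PS
isoflurane,E_BP,PB,IE_BP,NS,PM
isoflurane,E_BP,PB,IE_BP,PS,PB
isoflurane,E_BP,PB,IE_BP,PB,PB
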