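output_var,in1_var,in1_label,in2_var,in2_label,consequent_label
atracurium,E_MR,NB,IE_MR,NB,PB
atracurium,E_MR,NB,IE_MR,NS,PS
atracurium,E_MR,NB,IE_MR,PS,ZE
atracurium,E_MR,NB,IE_MR,PB,ZE
atracurium,E_MR,NM,IE_MR,NM,PM
atracurium,E_MR,NM,IE_MR,ZE,ZE
atracurium,E_MR,NM,IE_MR,PM,ZE
atracurium,E_MR,NS,IE_MR,NB,PB
atracurium,E_MR,NS,IE_MR,NS,PS
atracurium,E_MR,NS,IE_MR,PS,ZE
atracurium,E_MR,NS,IE_MR,PB,ZE
atracurium,E_MR,ZE,IE_MR,NM,PM
atracurium,E_MR,ZE,IE_MR,ZE,ZE
atracurium,E_MR,ZE,IE_MR,PM,ZE
atracurium,E_MR,PS,IE_MR,NB,PM
atracurium,E_MR,PS,IE_MR,NS,ZE
atracurium,E_MR,PS,IE_MR,PS,ZE
atracurium,E_MR,PS,IE_MR,PB,ZE
atracurium,E_MR,PM,IE_MR,NM,PM
atracurium,E_MR,PM,IE_MR,ZE,ZE
atracurium,E_MR,PM,IE_MR,PM,ZE
atracurium,E_MR,PB,IE_MR,NB,PM
atracurium,E_MR,PB,IE_MR,NS,ZE
atracurium,E_MR,PB,IE_MR,PS,ZE
atracurium,E_MR,PB,IE_MR,PB,ZE
atracurium,E_MR,NB,E_BP,NB,PB
atracurium,E_MR,NB,E_BP,NS,PM
atracurium,E_MR,NB,E_BP,PS,ZE
atracurium,E_MR,NB,E_BP,PB,ZE
atracurium,E_MR,NM,E_BP,NM,PM
atracurium,E_MR,NM,E_BP,ZE,ZE
atracurium,E_MR,NM,E_BP,PM,ZE
atracurium,E_MR,NS,E_BP,NB,PM
atracurium,E_MR,NS,E_BP,NS,PS
atracurium,E_MR,NS,E_BP,PS,ZE
atracurium,E_MR,NS,E_BP,PB,ZE
atracurium,E_MR,ZE,E_BP,NM,PM
atracurium,E_MR,ZE,E_BP,ZE,ZE
atracurium,E_MR,ZE,E_BP,PM,ZE
atracurium,E_MR,PS,E_BP,NB,PS
atracurium,E_MR,PS,E_BP,NS,PS
atracurium,E_MR,PS,E_BP,PS,ZE
atracurium,E_MR,PS,E_BP,PB,ZE
atracurium,E_MR,PM,E_BP,NM,PS
atracurium,E_MR,PM,E_BP,ZE,ZE
atracurium,E_MR,PM,E_BP,PM,ZE
atracurium,E_MR,PB,E_BP,NB,PS
atracurium,E_MR,PB,E_BP,NS,PS
atracurium,E_MR,PB,E_BP,PS,ZE
atracurium,E_MR,PB,E_BP,PB,ZE
atracurium,E_MR,NB,IE_BP,NB,PB
atracurium,E_MR,NB,IE_BP,NS,PS
atracurium,E_MR,NB,IE_BP,PS,ZE
atracurium,E_MR,NB,IE_BP,PB,ZE
atracurium,E_MR,NM,IE_BP,NM,PM
atracurium,E_MR,NM,IE_BP,ZE,ZE
atracurium,E_MR,NM,IE_BP,PM,ZE
atracurium,E_MR,NS,IE_BP,NB,PB
atracurium,E_MR,NS,IE_BP,NS,PS
atracurium,E_MR,NS,IE_BP,PS,ZE
atracurium,E_MR,NS,IE_BP,PB,ZE
atracurium,E_MR,ZE,IE_BP,NM,PM
atracurium,E_MR,ZE,IE_BP,ZE,ZE
atracurium,E_MR,ZE,IE_BP,PM,ZE
atracurium,E_MR,PS,IE_BP,NB,PB
atracurium,E_MR,PS,IE_BP,NS,PS
atracurium,E_MR,PS,IE_BP,PS,ZE
atracurium,E_MR,PS,IE_BP,PB,ZE
atracurium,E_MR,PM,IE_BP,NM,PM
atracurium,E_MR,PM,IE_BP,ZE,ZE
atracurium,E_MR,PM,IE_BP,PM,ZE
atracurium,E_MR,PB,IE_BP,NB,PB
atracurium,E_MR,PB,IE_BP,NS,PS
atracurium,E_MR,PB,IE_BP,PS,ZE
atracurium,E_MR,PB,IE_BP,PB,ZE
atracurium,IE_MR,NB,E_BP,NB,PB
atracurium,IE_MR,NB,E_BP,NS,PM
atracurium,IE_MR,NB,E_BP,PS,ZE
atracurium,IE_MR,NB,E_BP,PB,ZE
atracurium,IE_MR,NM,E_BP,NM,PM
atracurium,IE_MR,NM,E_BP,ZE,ZE
atracurium,IE_MR,NM,E_BP,PM,ZE
atracurium,IE_MR,NS,E_BP,NB,PB
atracurium,IE_MR,NS,E_BP,NS,PM
atracurium,IE_MR,NS,E_BP,PS,ZE
atracurium,IE_MR,NS,E_BP,PB,ZE
atracurium,IE_MR,ZE,E_BP,NM,PM
atracurium,IE_MR,ZE,E_BP,ZE,ZE
atracurium,IE_MR,ZE,E_BP,PM,ZE
atracurium,IE_MR,PS,E_BP,NB,PB
atracurium,IE_MR,PS,E_BP,NS,PS
atracurium,IE_MR,PS,E_BP,PS,ZE
atracurium,IE_MR,PS,E_BP,PB,ZE
atracurium,IE_MR,PM,E_BP,NM,PS
atracurium,IE_MR,PM,E_BP,ZE,ZE
atracurium,IE_MR,PM,E_BP,PM,ZE
atracurium,IE_MR,PB,E_BP,NB,PB
atracurium,IE_MR,PB,E_BP,NS,PS
atracurium,IE_MR,PB,E_BP,PS,ZE
atracurium,IE_MR,PB,E_BP,PB,ZE
atracurium,IE_MR,NB,IE_BP,NB,PB
atracurium,IE_MR,NB,IE_BP,NS,PS
atracurium,IE_MR,NB,IE_BP,PS,ZE
atracurium,IE_MR,NB,IE_BP,PB,ZE
atracurium,IE_MR,NM,IE_BP,NM,PM
atracurium,IE_MR,NM,IE_BP,ZE,ZE
atracurium,IE_MR,NM,IE_BP,PM,ZE
atracurium,IE_MR,NS,IE_BP,NB,PB
atracurium,IE_MR,NS,IE_BP,NS,PS
atracurium,IE_MR,NS,IE_BP,PS,ZE
atracurium,IE_MR,NS,IE_BP,PB,ZE
atracurium,IE_MR,ZE,IE_BP,NM,PM
atracurium,IE_MR,ZE,IE_BP,ZE,ZE
atracurium,IE_MR,ZE,IE_BP,PM,ZE
atracurium,IE_MR,PS,IE_BP,NB,PM
atracurium,IE_MR,PS,IE_BP,NS,ZE
atracurium,IE_MR,PS,IE_BP,PS,ZE
atracurium,IE_MR,PS,IE_BP,PB,ZE
atracurium,IE_MR,PM,IE_BP,NM,PM
atracurium,IE_MR,PM,IE_BP,ZE,ZE
atracurium,IE_MR,PM,IE_BP,PM,ZE
atracurium,IE_MR,PB,IE_BP,NB,PM
atracurium,IE_MR,PB,IE_BP,NS,ZE
atracurium,IE_MR,PB,IE_BP,PS,ZE
atracurium,IE_MR,PB,IE_BP,PB,ZE
atracurium,E_BP,NB,IE_BP,NB,ZE
atracurium,E_BP,NB,IE_BP,NS,ZE
atracurium,E_BP,NB,IE_BP,PS,ZE
atracurium,E_BP,NB,IE_BP,PB,ZE
atracurium,E_BP,NM,IE_BP,NM,ZE
atracurium,E_BP,NM,IE_BP,ZE,ZE
atracurium,E_BP,NM,IE_BP,PM,ZE
atracurium,E_BP,NS,IE_BP,NB,ZE
atracurium,E_BP,NS,IE_BP,NS,ZE
atracurium,E_BP,NS,IE_BP,PS,ZE
atracurium,E_BP,NS,IE_BP,PB,ZE
atracurium,E_BP,ZE,IE_BP,NM,ZE
atracurium,E_BP,ZE,IE_BP,ZE,ZE
atracurium,E_BP,ZE,IE_BP,PM,ZE
atracurium,E_BP,PS,IE_BP,NB,ZE
atracurium,E_BP,PS,IE_BP,NS,ZE
atracurium,E_BP,PS,IE_BP,PS,ZE
atracurium,E_BP,PS,IE_BP,PB,ZE
atracurium,E_BP,PM,IE_BP,NM,ZE
atracurium,E_BP,PM,IE_BP,ZE,ZE
atracurium,E_BP,PM,IE_BP,PM,ZE
atracurium,E_BP,PB,IE_BP,NB,ZE
atracurium,E_BP,PB,IE_BP,NS,ZE
atracurium,E_BP,PB,IE_BP,PS,ZE
atracurium,E_BP,PB,IE_BP,PB,ZE
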