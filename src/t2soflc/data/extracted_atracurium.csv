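output_var,in1_var,in1_label,in2_var,in2_label,consequent_label
atracurium,E_MR,NS,IE_MR,NS,PS
atracurium,E_MR,NS,IE_MR,ZE,PS
atracurium,E_MR,NS,IE_MR,PB,ZE
atracurium,E_MR,ZE,IE_MR,ZE,ZE
atracurium,E_MR,ZE,IE_MR,PM,ZE
atracurium,E_MR,NS,E_BP,NS,PS
atracurium,E_MR,NS,E_BP,ZE,PS
atracurium,E_MR,NS,E_BP,PS,ZE
atracurium,E_MR,NS,E_BP,PB,ZE
atracurium,E_MR,ZE,E_BP,ZE,PS
atracurium,E_MR,ZE,E_BP,PM,ZE
atracurium,E_MR,NS,IE_BP,NS,PS
atracurium,E_MR,ZE,IE_BP,ZE,ZE
atracurium,IE_MR,NS,E_BP,NS,PM
atracurium,IE_MR,NS,E_BP,PS,ZE
atracurium,IE_MR,NS,E_BP,PB,ZE
atracurium,IE_MR,ZE,E_BP,NS,PS
atracurium,IE_MR,ZE,E_BP,ZE,PS
atracurium,IE_MR,ZE,E_BP,PM,ZE
atracurium,IE_MR,ZE,E_BP,PB,ZE
atracurium,IE_MR,PS,E_BP,NS,PS
atracurium,IE_MR,PS,E_BP,ZE,PS
atracurium,IE_MR,PM,E_BP,NS,PS
atracurium,IE_MR,PM,E_BP,ZE,PS
atracurium,IE_MR,PB,E_BP,NS,PS
atracurium,IE_MR,PB,E_BP,ZE,ZE
atracurium,IE_MR,NS,IE_BP,NS,PS
atracurium,IE_MR,ZE,IE_BP,NS,PS
atracurium,IE_MR,ZE,IE_BP,ZE,PS
atracurium,IE_MR,PS,IE_BP,NS,ZE
atracurium,IE_MR,PM,IE_BP,ZE,ZE
atracurium,IE_MR,PB,IE_BP,NS,ZE
atracurium,E_BP,NS,IE_BP,NS,ZE
atracurium,E_BP,ZE,IE_BP,NS,ZE
atracurium,E_BP,ZE,IE_BP,ZE,ZE
atracurium,E_BP,PM,IE_BP,ZE,ZE
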