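error,NB,NM,NS,ZE,PS,PM,PB
NB,NB,NB,NB,NM,NM,NS,ZE
NM,NB,NB,NM,NM,NS,ZE,PS
NS,NB,NB,NS,NS,ZE,PS,PM
ZE,NB,NM,ZE,ZE,PS,PM,PB
PS,NM,NS,ZE,PS,PS,PB,PB
PM,NS,ZE,PS,PM,PM,PB,PB
PB,ZE,PS,PM,PM,PB,PB,PB
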