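plant_id	B224C4P2	RGR1963	Ca_Sb07g023910	Ca_Sb07g024020	Ca_Sb07g023810	Ca_Sb07g023630	Ca_Sb07g023520	Ca_Sb07g023430	PSMP344
#mode	codominant	codominant	codominant	codominant	codominant	codominant	codominant	codominant	codominant
r01	AA	AA	AA	AA	AA	AB	AB	AB	AB
r02	BB	BB	BB	BB	BB	AB	AB	AB	AB
r03	AB	AB	AB	AB	AB	BB	BB	BB	BB
r04	AB	AB	AB	AB	AB	AA	AA	AA	AA
r05	AA	AA	AA	AA	AA	AA	AA	AA	AB
r06	BB	BB	BB	BB	BB	BB	BB	BB	AB
r07	AB	AB	AB	AB	AB	AB	AB	AB	AA
r08	AB	AB	AB	AB	AB	AB	AB	AB	BB
r09	AA	AA	AA	AA	AA	AA	AA	AA	AB
r10	BB	BB	BB	BB	BB	BB	BB	BB	AB
r11	AB	AB	AB	AB	AB	AB	AB	AB	BB
r12	AB	AB	AB	AB	AB	AB	AB	AB	AA
r13	BB	BB	BB	BB	BB	BB	BB	BB	AB
r14	AA	AA	AA	AA	AA	AA	AA	AA	AB
r15	AB	AB	AB	AB	AB	AB	AB	AB	AA
r16	BB	BB	BB	BB	BB	BB	BB	BB	AB
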