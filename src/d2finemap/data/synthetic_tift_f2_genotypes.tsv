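plant_id	B224C4P2	Ca_Sb07g023430	Ca_Sb07g023440	Ca_Sb07g023520	Ca_Sb07g023630	Ca_Sb07g023810	Ca_Sb07g023840	Ca_Sb07g023850	Ca_Sb07g023910	PSMP344	PSMP305
#mode	codominant	codominant	codominant	codominant	codominant	codominant	dominant	codominant	codominant	codominant	codominant
1	AA	AA	AA	AA	AA	AA	A-	AA	AA	AB	AB
55	AB	AB	AB	AB	AB	AB	A-	AB	AB	AA	AA
177	AA	AA	AA	AA	AA	AA	A-	AA	AA	AB	AB
263	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB	AB
310	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB	AB
320	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB	AB
344	AA	AA	AA	AA	AA	AA	A-	AA	AA	AB	AB
349	AB	AB	AB	AB	AB	AB	A-	AB	AB	AA	AA
374	AA	AA	AA	AA	AA	AA	A-	AA	AA	AA	AB
477	AA	AA	AA	AA	AA	AA	A-	AA	AA	AA	AB
479	AB	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB
486	AB	AB	AB	AB	AB	AB	A-	AB	AB	AA	AA
496	AB	AB	AB	AB	AB	AB	A-	AB	AB	BB	BB
514	AB	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB
612	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB
701	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB	AB
778	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB
787	AA	AB	AB	AB	AB	AB	A-	AB	AB	AB	AB
812	AB	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB
900	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB	AB
914	BB	AB	AB	AB	AB	AB	A-	AB	AB	AB	AB
924	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB	AB
930	AB	BB	BB	BB	BB	BB	BB	BB	BB	BB	BB
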