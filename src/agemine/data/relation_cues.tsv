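cue	type	priority
onset	AGE_OF_ONSET	1
first appeared	AGE_OF_ONSET	1
developed	AGE_OF_ONSET	1
began	AGE_OF_ONSET	1
debut	AGE_OF_ONSET	1
diagnosed	AGE_OF_DIAGNOSIS	2
diagnosis	AGE_OF_DIAGNOSIS	2
detected	AGE_OF_DIAGNOSIS	2
observed	AGE_OF_OBSERVATION	3
presented with	AGE_OF_OBSERVATION	3
presenting	AGE_OF_OBSERVATION	3
found to have	AGE_OF_OBSERVATION	3
seen in	AGE_OF_OBSERVATION	3
occurred	AGE_OF_OCCURRENCE	4
occurrence	AGE_OF_OCCURRENCE	4
incidence	AGE_OF_OCCURRENCE	4
events	AGE_OF_OCCURRENCE	4
evaluated	AGE_OF_EVALUATION	5
assessed	AGE_OF_EVALUATION	5
examined	AGE_OF_EVALUATION	5
screened	AGE_OF_EVALUATION	5
measured	AGE_OF_EVALUATION	5
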