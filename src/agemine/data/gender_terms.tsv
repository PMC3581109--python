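term	gender
man	MALE
men	MALE
male	MALE
males	MALE
boy	MALE
boys	MALE
woman	FEMALE
women	FEMALE
female	FEMALE
females	FEMALE
girl	FEMALE
girls	FEMALE
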