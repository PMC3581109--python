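name	role	priority	pattern
range_between	range	1	between {N1} and {N2}\s*{U}(?:\s+(?:of age|old))?
range_to_old	range	1	{N1}\s*(?:-|–|to)\s*{N2}[\s-]*{U}[\s-]*(?:old|of age)
range_aged_unit	range	1	aged?\s+{N1}\s*(?:-|–|to)\s*{N2}\s*{U}
range_aged_bare	range	1	aged\s+{N1}\s*(?:-|–|to)\s*{N2}\b
range_from_to	range	1	from\s+{N1}\s+to\s+{N2}\s*{U}(?:\s+(?:of age|old))?
range_to_plain	range	1	{N1}\s+to\s+{N2}\s+{U}\b
open_low_prefix	open_low	2	(?:under|below|less than|younger than|up to|no more than)\s+{N1}\s*{U}(?:\s+(?:of age|old))?
open_low_suffix	open_low	2	{N1}\s*{U}\s+(?:or less|or younger|or under|and under|and younger)
open_high_prefix	open_high	2	(?:over|above|more than|older than|at least)\s+{N1}\s*{U}(?:\s+(?:of age|old))?
open_high_suffix	open_high	2	{N1}\s*{U}\s+(?:or more|or older|or over|and over|and older|and above)
point_unit_old	point	3	{N1}[\s-]+{U}[\s-]+old
point_aged_unit	point	3	aged\s+{N1}\s*{U}
point_of_age	point	3	{N1}\s+{U}\s+of age
point_aged_bare	point	3	aged\s+{N1}\b
point_at_age	point	3	at\s+(?:the\s+)?age\s+(?:of\s+)?{N1}\b
point_age_of	point	3	age\s+of\s+{N1}\b
mean_age	mean	4	(?:mean|median|average)\s+age(?:\s+(?:was|is))?(?:\s+of)?\s+{N1}(?:\s*{U})?
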