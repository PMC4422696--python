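subject	reference	direction_of_reference	enrichment	p_value
Phenoxybenzamine	resveratrol	glucose_improving	0.799	0.034
Nabumetone	resveratrol	glucose_improving	0.576	0.02
Niflumic Acid	resveratrol	glucose_improving	0.484	0.018
Perhexiline	resveratrol	glucose_improving	0.697	0.00006
Idazoxan	gliclazide	anti_diabetic	0.728	0.011
D-cycloserine	gliclazide	anti_diabetic	0.56	0.036
Diflorasone	streptozocin	diabetogenic	-0.709	0.015
Diflunisal	glimepiride	anti_diabetic	0.626	0.049
Valdecoxib	metformin	anti_diabetic	0.412	0.047
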