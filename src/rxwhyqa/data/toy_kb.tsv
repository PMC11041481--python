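acetaminophen	pain
acetaminophen	fever
senna	constipation
oxycodone	pain
morphine	pain
coumadin	afib
lasix	fluid overload
vancomycin	infection
albuterol sulfate	wheeze
albuterol sulfate	sob
metoprolol	hypertension
amlodipine	hypertension
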