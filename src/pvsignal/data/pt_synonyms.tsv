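raw	canonical
anaemia	anemia
diarrhea	diarrhoea
edema peripheral	oedema peripheral
dyspnea	dyspnoea
hyponatremia	hyponatraemia
uterine bleeding	uterine haemorrhage
peripheral neuropathy	neuropathy peripheral
cervix cancer	cervix carcinoma
ecog performance status worsened	eastern cooperative oncology group performance status worsened
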