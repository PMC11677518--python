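variant	canonical
Blood calcium increased	Hypercalcaemia
Hypercalcemia	Hypercalcaemia
Diarrhea	Diarrhoea
Dyspnea	Dyspnoea
Paresthesia	Paraesthesia
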