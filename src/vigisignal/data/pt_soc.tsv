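pt	soc
Hypercalcaemia	Metabolism and nutrition disorders
Dehydration	Metabolism and nutrition disorders
Decreased appetite	Metabolism and nutrition disorders
Abdominal pain	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Pancreatitis	Gastrointestinal disorders
Fatigue	General disorders and administration site conditions
Pain	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Drug ineffective	Product issues
Off-label use	Product issues
Headache	Nervous system disorders
Paraesthesia	Nervous system disorders
Overdose	Injury, poisoning and procedural complications
Toxicity to various agents	Injury, poisoning and procedural complications
Accidental overdose	Injury, poisoning and procedural complications
Intentional overdose	Injury, poisoning and procedural complications
Acute kidney injury	Renal and urinary disorders
Renal impairment	Renal and urinary disorders
Renal failure	Renal and urinary disorders
Nephrocalcinosis	Renal and urinary disorders
Nephrolithiasis	Renal and urinary disorders
Rash	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Urticaria	Skin and subcutaneous tissue disorders
Erythema	Skin and subcutaneous tissue disorders
Confusional state	Psychiatric disorders
Insomnia	Psychiatric disorders
Anxiety	Psychiatric disorders
Depression	Psychiatric disorders
Arrhythmia	Cardiac disorders
Bradycardia	Cardiac disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Choking	Respiratory, thoracic and mediastinal disorders
Neoplasm malignant	Neoplasms benign, malignant and unspecified
Blood parathyroid hormone increased	Investigations
Blood calcium decreased	Investigations
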