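pt	soc
malignant neoplasm progression	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
product use in unapproved indication	Injury, poisoning and procedural complications
anemia	Blood and lymphatic system disorders
neutropenia	Blood and lymphatic system disorders
adverse event	General disorders and administration site conditions
neuropathy peripheral	Nervous system disorders
inappropriate schedule of product administration	Injury, poisoning and procedural complications
skin disorder	Skin and subcutaneous tissue disorders
neutrophil count decreased	Investigations
myelosuppression	Blood and lymphatic system disorders
febrile neutropenia	Blood and lymphatic system disorders
hypothyroidism	Endocrine disorders
drug eruption	Skin and subcutaneous tissue disorders
immune-mediated enterocolitis	Gastrointestinal disorders
female genital tract fistula	Reproductive system and breast disorders
renal impairment	Renal and urinary disorders
intestinal perforation	Gastrointestinal disorders
platelet count decreased	Investigations
urogenital fistula	Reproductive system and breast disorders
colitis	Gastrointestinal disorders
immune-mediated endocrinopathy	Endocrine disorders
hepatic function abnormal	Hepatobiliary disorders
transfusion	Surgical and medical procedures
proteinuria	Renal and urinary disorders
immune-mediated hepatic disorder	Hepatobiliary disorders
immune-mediated hypothyroidism	Endocrine disorders
erythema multiforme	Skin and subcutaneous tissue disorders
eastern cooperative oncology group performance status worsened	General disorders and administration site conditions
cytokine release syndrome	Immune system disorders
cervix carcinoma recurrent	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
immune-mediated cholangitis	Hepatobiliary disorders
ureteral stent insertion	Surgical and medical procedures
immune-mediated adrenal insufficiency	Endocrine disorders
immune-mediated hypophysitis	Endocrine disorders
immune-mediated encephalitis	Nervous system disorders
gastroenteritis radiation	Gastrointestinal disorders
enanthema	Skin and subcutaneous tissue disorders
duodenal perforation	Gastrointestinal disorders
cortisol decreased	Investigations
packed red blood cell transfusion	Surgical and medical procedures
immune-mediated hepatitis	Hepatobiliary disorders
lymphadenopathy	Blood and lymphatic system disorders
pyelonephritis	Infections and infestations
uterine haemorrhage	Reproductive system and breast disorders
gastrointestinal perforation	Gastrointestinal disorders
cervix carcinoma	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
cervical cancer	Neoplasms benign, malignant and unspecified (incl cysts and polyps)
nausea	Gastrointestinal disorders
vomiting	Gastrointestinal disorders
diarrhoea	Gastrointestinal disorders
fatigue	General disorders and administration site conditions
pyrexia	General disorders and administration site conditions
headache	Nervous system disorders
rash	Skin and subcutaneous tissue disorders
pruritus	Skin and subcutaneous tissue disorders
dizziness	Nervous system disorders
dyspnoea	Respiratory, thoracic and mediastinal disorders
cough	Respiratory, thoracic and mediastinal disorders
constipation	Gastrointestinal disorders
abdominal pain	Gastrointestinal disorders
decreased appetite	Metabolism and nutrition disorders
arthralgia	Musculoskeletal and connective tissue disorders
myalgia	Musculoskeletal and connective tissue disorders
insomnia	Psychiatric disorders
hypertension	Vascular disorders
hyponatraemia	Metabolism and nutrition disorders
pneumonia	Infections and infestations
urinary tract infection	Infections and infestations
sepsis	Infections and infestations
dehydration	Metabolism and nutrition disorders
back pain	Musculoskeletal and connective tissue disorders
oedema peripheral	General disorders and administration site conditions
drug ineffective	General disorders and administration site conditions
alopecia	Skin and subcutaneous tissue disorders
stomatitis	Gastrointestinal disorders
thrombocytopenia	Blood and lymphatic system disorders
asthenia	General disorders and administration site conditions
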