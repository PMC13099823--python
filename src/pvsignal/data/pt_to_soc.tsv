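# Mock MedDRA-style preferred-term -> primary system organ class map (synthetic;
# real MedDRA is license-gated).  Tab-separated: pt<TAB>soc, case-insensitive.
stomatitis	gastrointestinal disorders
mucosal inflammation	general disorders and administration site conditions
pyrexia	general disorders and administration site conditions
malaise	general disorders and administration site conditions
oedema peripheral	general disorders and administration site conditions
chest pain	general disorders and administration site conditions
pain	general disorders and administration site conditions
discomfort	general disorders and administration site conditions
catheter site cellulitis	general disorders and administration site conditions
platelet count decreased	investigations
platelet count increased	investigations
neutrophil count decreased	investigations
white blood cell count decreased	investigations
haemoglobin decreased	investigations
alanine aminotransferase increased	investigations
aspartate aminotransferase increased	investigations
blood lactate dehydrogenase increased	investigations
blood chloride decreased	investigations
blood urea increased	investigations
blood bilirubin increased	investigations
activated partial thromboplastin time prolonged	investigations
weight decreased	investigations
anaemia	blood and lymphatic system disorders
neutropenia	blood and lymphatic system disorders
thrombocytopenia	blood and lymphatic system disorders
pancytopenia	blood and lymphatic system disorders
lymphopenia	blood and lymphatic system disorders
febrile neutropenia	blood and lymphatic system disorders
myelosuppression	blood and lymphatic system disorders
diarrhoea	gastrointestinal disorders
nausea	gastrointestinal disorders
vomiting	gastrointestinal disorders
constipation	gastrointestinal disorders
abdominal pain	gastrointestinal disorders
abdominal pain upper	gastrointestinal disorders
intestinal ischaemia	gastrointestinal disorders
small intestinal perforation	gastrointestinal disorders
oral disorder	gastrointestinal disorders
dry mouth	gastrointestinal disorders
malignant neoplasm progression	neoplasms benign, malignant and unspecified (incl cysts and polyps)
tumour lysis syndrome	metabolism and nutrition disorders
decreased appetite	metabolism and nutrition disorders
dehydration	metabolism and nutrition disorders
hypoalbuminaemia	metabolism and nutrition disorders
malnutrition	metabolism and nutrition disorders
sepsis	infections and infestations
herpes zoster	infections and infestations
urinary tract infection	infections and infestations
pneumonia	infections and infestations
toxic epidermal necrolysis	skin and subcutaneous tissue disorders
stevens-johnson syndrome	skin and subcutaneous tissue disorders
rash	skin and subcutaneous tissue disorders
pruritus	skin and subcutaneous tissue disorders
urticaria	skin and subcutaneous tissue disorders
alopecia	skin and subcutaneous tissue disorders
skin lesion	skin and subcutaneous tissue disorders
blister	skin and subcutaneous tissue disorders
skin exfoliation	skin and subcutaneous tissue disorders
epistaxis	respiratory, thoracic and mediastinal disorders
dyspnoea	respiratory, thoracic and mediastinal disorders
cough	respiratory, thoracic and mediastinal disorders
headache	nervous system disorders
dizziness	nervous system disorders
somnolence	nervous system disorders
tremor	nervous system disorders
fatigue	general disorders and administration site conditions
hepatotoxicity	hepatobiliary disorders
hepatic function abnormal	hepatobiliary disorders
arthralgia	musculoskeletal and connective tissue disorders
myalgia	musculoskeletal and connective tissue disorders
back pain	musculoskeletal and connective tissue disorders
insomnia	psychiatric disorders
anxiety	psychiatric disorders
hypertension	vascular disorders
palpitations	cardiac disorders
feeding disorder	metabolism and nutrition disorders
therapeutic response decreased	general disorders and administration site conditions
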