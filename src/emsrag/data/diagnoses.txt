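Acute appendicitis
Atrial fibrillation
Acute bronchitis
Pneumonia
Pulmonary embolism
Acute cystitis
Renal colic
Migraine
Syncope
Sepsis
Hypoglycemia
Hyperglycemia
Acute pancreatitis
Cholecystitis
Gastroenteritis
Peptic ulcer
Anaphylaxis
Asthma exacerbation
COPD exacerbation
Heart failure
Myocardial infarction
Unstable angina
Ischemic stroke
Transient ischemia
Seizure disorder
Alcohol intoxication
Opioid overdose
Ankle fracture
Wrist fracture
Rib fracture
Concussion
Cellulitis
Deep vein thrombosis
Hyperkalemia
Dehydration
Urinary retention
Acute otitis media
Kidney infection
Lumbar strain
Hip dislocation
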