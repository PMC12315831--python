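Aspirin 81mg TAB
PredniSONE 20mg TAB
Ibuprofen 400mg TAB
Paracetamol 500mg
Morphine 2mg INJ
Fentanyl 50mcg INJ
Ondansetron 4mg
Metoprolol 25mg
Lisinopril 10mg
Amlodipine 5mg
Furosemide 40mg
Insulin glargine
Metformin 500mg
Albuterol inhaler
Ipratropium NEB
Ceftriaxone 1g INJ
Azithromycin 250mg
Amoxicillin 500mg
Heparin 5000u INJ
Enoxaparin 40mg
Warfarin 5mg
Clopidogrel 75mg
Atorvastatin 20mg
Pantoprazole 40mg
Omeprazole 20mg
Diazepam 5mg
Lorazepam 1mg INJ
Ketorolac 15mg INJ
Naloxone 0.4mg INJ
Epinephrine 0.3mg
Magnesium 2g INJ
Dexamethasone 4mg
Hydralazine 10mg
Labetalol 20mg INJ
Nitroglycerin SL
Vitamin D 1000u
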