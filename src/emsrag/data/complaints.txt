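Chest pain
Shortness of breath
Abdominal pain
Headache
Dizziness
Back pain
Leg swelling
Fever and chills
Nausea and vomiting
Palpitations
Weakness
Confusion
Fainting spell
Ankle injury
Wrist injury
Difficulty breathing
Severe allergy
Burning urination
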