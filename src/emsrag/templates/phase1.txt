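[[dialogue-section]] phase=1 tone={tone}
Scene: first contact in the ambulance; responders assess the patient.
{tone_instruction}
Facts:
- complaint is {chief_complaint}
- patient gender is {gender}
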