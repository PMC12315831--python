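[[dialogue-section]] phase=4 tone={tone}
Scene: arrival at the hospital; handover to the receiving team.
{tone_instruction}
Facts:
{diagnoses_lines}
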