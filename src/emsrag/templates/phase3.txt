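[[dialogue-section]] phase=3 tone={tone}
Scene: medication administration and re-measurement of vital signs.
{tone_instruction}
Facts:
{meds_administered_lines}
- temperature is {temperature_reassess}
- heart rate is {heartrate_reassess}
- respiration rate is {resprate_reassess}
- oxygen saturation is {o2sat_reassess}
- blood pressure is {bp_reassess}
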