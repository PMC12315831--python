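[[dialogue-section]] phase=2 tone={tone}
Scene: triage; staff measure the initial vital signs and review home medication.
{tone_instruction}
Facts:
- temperature is {temperature_triage}
- heart rate is {heartrate_triage}
- respiration rate is {resprate_triage}
- oxygen saturation is {o2sat_triage}
- blood pressure is {bp_triage}
- pain score is {pain_triage}
{meds_reported_lines}
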