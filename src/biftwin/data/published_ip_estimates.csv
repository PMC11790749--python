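level,A,C,E
general,0.08,0.02,0.18
inattention,0.03,0.01,0.10
hyperactivity,0.03,0.01,0.05
unique,0.02,0.00,0.46
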