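factor,A,C,E
general,0.40,,0.60
inattention,0.42,,0.58
hyperactivity,0.33,,0.67
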