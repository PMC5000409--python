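# One trial: 25 practices of 620 patients, patient refusal 0.2 concentrated
# in the lowest-risk patients (high correlation tier, negative sign).
[refusal]
p = 0.2
tier_p = high
sign_p = negative
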