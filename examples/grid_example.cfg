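# Two scenarios at patient refusal 0.2 (uncorrelated vs strongly
# risk-correlated refusal), 100 replicates each, ITT and 2SRI with the
# lognormal frailty Cox model.
[refusal]
p = 0.2
tier_p = zero, high
sign_p = negative

[run]
model = lognormal
methods = itt, 2sri
reps = 100
base_seed = 3
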