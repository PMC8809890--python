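# Scaled-profile run of the "ef" double mutant (adjacent E->D substitutions)
# with the default energetics.  Every key shown here is optional; an empty
# file reproduces the full default (production-length wild-type) setup.

[mutations]
pattern = "ef"
# sensitivity variants of the Asp carrier, uncomment to use:
# A_ASP = 2.5
# pKa_ASP = 7.8

[environment]
pH_IMS = 7.0
pH_matrix = 8.0
delta_psi_mV = 150.0

[run]
desk = true          # 1000 rounds x 1e4 MD steps, rescaled dt
rounds = 1500
seed = 1
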