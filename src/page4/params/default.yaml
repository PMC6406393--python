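g_W: 0.01462098120373297
k_H: 0.01
k_C: 0.05
delta_W: 0.0046209812037329686
delta_H: 0.003
delta_C: 0.02
delta_K: 0.02
delta_A: 0.02
g_A: 0.02
g_K: 0.02
H0: 0.4
n_H: 8.0
A0: 0.5
n_A: 8.0
beta_OE: 0.05
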