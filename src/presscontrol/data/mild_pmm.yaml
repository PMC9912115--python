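xi1: 0.036
xi2: 0.03
rho_b: 0.39
rho_c: 0.29
kaw_a: 0.77
kaw_inv_b: 10.26
rho_t: 1.53
eps0: 0.08
rho_c_eps: 0.57
sigma0: 11.67
rho_c0: 0.57
rho_cinf: 0.61
b1: 0.31
b2: 0.38
b3: 8.4
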