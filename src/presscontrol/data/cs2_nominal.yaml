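xi1: 0.036
xi2: 0.03
rho_b: 0.365
rho_c: 0.265
kaw_a: 0.8
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
rho_b_inf: 0.45
rho_b_0: 0.33
r1: 0.361
r2: 1.394
r3: 23.326
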