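name: eq6a_alpha_all
version: 1
target: alpha
# Quartic of the oxygen milk/farm-water fractionation factor on day number,
# all sheds (including outdoor grazing). s_yx and u_pred in permil (10^3 alpha).
coefficients: [2.072e-12, -1.689e-9, 3.867e-7, -1.770e-5, 1.0012]
n: 108
s_yx_permil: 0.50
r2: 0.69
u_pred_permil: 0.51
excluded_sheds: []
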