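name: eq6b_alpha_indoor
version: 1
target: alpha
# Quartic of the oxygen milk/farm-water fractionation factor on day number,
# outdoor-grazing sheds excluded (indoor herds). Default for step two of the
# provenance check. s_yx and u_pred in permil (10^3 alpha).
coefficients: [2.096e-12, -1.627e-9, 3.540e-7, -1.467e-5, 1.0012]
n: 84
s_yx_permil: 0.41
r2: 0.72
u_pred_permil: 0.42
excluded_sheds: ["Castelnovo", "Baiso"]
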