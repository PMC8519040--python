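name: eq5_milk_d18O
version: 1
target: milk_d18O
# Quartic of 10^3 delta(18O/16O)_M (permil vs VSMOW) on non-leap day number,
# fitted on 84 indoor shed-months (outdoor-grazing sheds excluded).
coefficients: [1.55e-9, -1.34e-6, 3.24e-4, -1.62e-2, -7.91]
n: 84
s_yx_permil: 0.92
r2: 0.30
u_pred_permil: null
excluded_sheds: ["Castelnovo", "Baiso"]
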