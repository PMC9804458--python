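# Default parameter means for the Christmas Island red-tailed tropicbird
# predation model (feral cats and black rats).
#
# Keys are the ASCII-transliterated model symbols. Derived parameters
# (beta, mu_H, T_mat, mass_H, metdemand_C, metdemand_R) are computed from
# these primitives at load time unless explicitly overridden here.

# --- tropicbird demography ---
N_A0: 2800        # adult birds at breeding-season start [individuals]
T_I: 42           # incubation time [days]
T_H: 90           # hatchling time in nest [days]
T_B: 122          # breeding-season duration [days]
alpha_M: 3        # age at reproductive maturity [years]
alpha_R: 15       # life span [years]
nu: 0.99          # proportion of viable eggs
mu_A: 0.125       # annual natural adult mortality [proportion / yr]
mu_J: 0.20        # annual natural juvenile mortality [proportion / yr]

# --- predator diet fractions [proportion of daily intake] ---
preypref_A_C: 0.382   # adult bird in cat diet
preypref_H_C: 0.382   # hatchling in cat diet
preypref_H_R: 0.02    # hatchling in rat diet
preypref_E_R: 0.04    # egg in rat diet

# --- masses [g / individual] ---
mass_C: 3250
mass_R: 132
mass_A: 700
mass_E: 66.2

# --- prey energy densities [kJ / g] ---
energy_A: 10.9
energy_H: 10.9
energy_E: 29

# --- field-metabolic-rate allometry (demand = coeff * mass^exp, kJ/day) ---
allom_coeff_C: 1.67
allom_exp_C: 0.869
allom_coeff_R: 5.48
allom_exp_R: 0.712
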