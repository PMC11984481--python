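"""Physical and model constants shared across the package.

All equation-of-state work is done in SI units (K, Pa, m^3/mol,
Pa·m^6/mol^2).  The COSMO-RS layer works in the units its universal
constants were fitted in (kJ/mol, Å^2, e/Å^2); the conversion happens
once, at the module boundary.
"""

#: Universal gas constant, J mol^-1 K^-1.
R = 8.31446

#: Universal gas constant, kJ mol^-1 K^-1 (COSMO-RS layer).
R_KJ = R * 1e-3

#: Peng-Robinson critical-point constants.
OMEGA_A = 0.45724
OMEGA_B = 0.07780

#: Huron-Vidal infinite-pressure packing constant for the PR form,
#: Lambda = ln((2+sqrt2)/(2-sqrt2)) / (2 sqrt2).
LAMBDA_HV = 0.6232252401402305

#: kcal <-> kJ.
KCAL_PER_KJ = 1.0 / 4.184
KJ_PER_KCAL = 4.184

#: Reference temperature for the hydrogen-bond temperature damping, K.
T_REF_HB = 298.15

#: Universal group-contribution exponents (one per predicted property).
BETA_AC = 0.67
BETA_B = 0.80
BETA_A0 = 0.48
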