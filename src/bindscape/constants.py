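"""Physical constants and package-wide unit conventions.

Units are fixed across the package: lengths in Angstrom, energies in
kcal/mol, charges in units of the elementary charge, temperatures in
Kelvin, times in nanoseconds.
"""

#: Coulomb conversion factor, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Gas constant / Boltzmann constant, kcal/(mol*K).
GAS_CONSTANT = 1.98720425e-3

#: Dielectric offset subtracted from intrinsic Born radii before
#: descreening integrals (Amber convention), Angstrom.
GB_RADIUS_OFFSET = 0.09

#: Solute interior dielectric used by the MM-GBSA route.
EPS_IN_DEFAULT = 1.0

#: Solvent dielectric.
EPS_OUT_DEFAULT = 78.5

#: Temperature used for converting inhibition constants to free energies, K.
TEMPERATURE_EXP_DEFAULT = 298.15

#: Temperature used to scale free-energy landscapes, K.
TEMPERATURE_SIM_DEFAULT = 300.0
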