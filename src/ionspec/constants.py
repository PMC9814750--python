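"""Physical constants (CODATA 2018) and unit conversion factors."""

# CODATA 2018 exact values
K_B = 1.380649e-23          # Boltzmann constant, J/K
N_A = 6.02214076e23         # Avogadro constant, 1/mol
EPS_0 = 8.8541878128e-12    # vacuum permittivity, F/m
C_LIGHT_CM_PS = 0.0299792458  # speed of light, cm/ps

DEBYE = 3.33564e-30         # 1 Debye in C*m

# wavenumber (cm^-1) -> angular frequency (rad/ps)
WN_TO_ANG = 2.0 * 3.141592653589793 * C_LIGHT_CM_PS

DEFAULT_TEMPERATURE_K = 298.15
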