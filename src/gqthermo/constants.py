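"""Physical constants (CODATA 2018 exact values where defined) and unit helpers."""

# Gas constant in the unit system of the thermodynamic tables (kcal / mol / K).
R_KCAL: float = 1.98720425e-3

#: Offset between Celsius and Kelvin scales.
CELSIUS_OFFSET: float = 273.15

#: Reference temperature "25 degC" for dG and TdS reporting, in Kelvin.
TREF_25C: float = 298.15

# SI constants (CODATA 2018; e, k and c are exact by definition since the
# 2019 SI redefinition, eps0 is the 2018 recommended value).
ELEMENTARY_CHARGE_C: float = 1.602176634e-19   # C
BOLTZMANN_J_PER_K: float = 1.380649e-23        # J / K
VACUUM_PERMITTIVITY_F_PER_M: float = 8.8541878128e-12  # F / m
SPEED_OF_LIGHT_M_PER_S: float = 299792458.0    # m / s


def celsius_to_kelvin(t_c):
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k):
    return t_k - CELSIUS_OFFSET
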