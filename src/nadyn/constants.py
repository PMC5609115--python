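"""Physical constants and unit-conversion factors.

Unit conventions used throughout the package:

======================  ==========
quantity                unit
======================  ==========
geometry                um
time                    ms
voltage                 mV
concentration           mM
current density         mA/cm^2
point current           nA
conductance (point)     uS
conductance density     S/cm^2
capacitance (point)     nF
capacitance density     uF/cm^2
resistance              MOhm
pump surface density    mol/cm^2
diffusion coefficient   um^2/ms
======================  ==========
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

#: default "physiological temperature" (K)
BODY_TEMPERATURE = 310.15

# mA/cm^2 * um^2 -> nA
DENSITY_TO_POINT = 1e-2

# nA for 1 ms into 1 um^3 -> mM (divide by valence * FARADAY first);
# derivation: 1 nA*ms = 1e-12 C; 1 um^3 = 1e-15 L; C/(F) = mol;
# mol / L = M = 1e3 mM  =>  factor 1e-12/1e-15*1e3 = 1e6
CHARGE_TO_CONC = 1e6

# mol/(cm^2 ms) surface flux * (area um^2 / volume um^3) -> mM/ms
# mol/(cm^2 ms) * 1/um = 1e4 mol/(cm^3 ms) = 1e4 * 1e6 mM/ms
SURFACE_FLUX_TO_CONC = 1e10

# C/(cm^2 ms) -> mA/cm^2
CHARGE_FLUX_TO_CURRENT = 1e6


def thermal_voltage(temperature: float) -> float:
    """RT/F in mV at the given temperature (K)."""
    return GAS_CONSTANT * temperature / FARADAY * 1e3
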