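"""Physical constants in the repository-wide unit system: eV, nm, fs.

Velocities are nm/fs, masses eV·fs²/nm² (m = m c² / c² with c in nm/fs),
so KE = ½ m v² comes out in eV with no conversion factors anywhere else.
"""

#: speed of light, nm/fs
C_LIGHT = 299.792458

#: electron rest energy, eV
ELECTRON_REST_ENERGY = 510_998.95

#: electron mass, eV·fs²/nm²
ELECTRON_MASS = ELECTRON_REST_ENERGY / C_LIGHT**2  # 5.685630...

#: Boltzmann constant, eV/K
K_BOLTZMANN = 8.617333e-5

#: Coulomb constant e²/(4πε₀), eV·nm
COULOMB_CONSTANT = 1.43996

#: molecular number density of liquid water at 1 g/cm³, nm⁻³
WATER_NUMBER_DENSITY = 33.43

#: Bohr radius, nm
BOHR_RADIUS = 0.0529177

#: Rydberg energy, eV
RYDBERG = 13.6057


def speed_from_energy(kinetic_energy_ev):
    """Non-relativistic electron speed (nm/fs) from kinetic energy (eV)."""
    import numpy as np

    return np.sqrt(2.0 * np.asarray(kinetic_energy_ev) / ELECTRON_MASS)
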