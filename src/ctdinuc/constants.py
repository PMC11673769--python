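"""Physical constants and unit conversions used throughout the package.

Energies are carried in eV, times in ps, wavelengths in nm, concentrations
in mol L^-1 and optical paths in cm unless a name says otherwise.
"""

import math

#: Boltzmann constant, eV/K (CODATA).
KB_EV_PER_K = 8.617333262e-5

#: "Room temperature" default, K.  k_B * 293 K = 0.02525 eV, the thermal
#: energy scale against which conformer energy gaps are judged.
ROOM_TEMPERATURE_K = 293.0

#: Hartree in eV.
HARTREE_EV = 27.211386

#: Photon wavelength-energy product: E[eV] = NM_EV / lambda[nm].
NM_EV = 1239.84198

#: FWHM -> Gaussian sigma.
FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))


def nm_to_ev(wavelength_nm):
    """Convert photon wavelength (nm) to energy (eV). Self-inverse form."""
    return NM_EV / wavelength_nm


def ev_to_nm(energy_ev):
    """Convert photon energy (eV) to wavelength (nm)."""
    return NM_EV / energy_ev
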