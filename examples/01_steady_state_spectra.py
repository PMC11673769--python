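"""Broadened absorption and CD spectra of the dominant conformers.

Loads the packaged stick tables for anti-syn AG and anti-anti GA, applies
the -0.65 eV calibration shift and 0.4 eV FWHM Gaussian broadening, and
compares the resulting band maxima.
"""

import ctdinuc as cd

cfg = cd.BroadeningConfig()  # fwhm 0.4 eV, shift -0.65 eV
grid = cd.steady_state_grid()

for dinuc in ("AG", "GA"):
    model = cd.reference_model(dinuc)
    absorption = cd.absorption_spectrum(model, cfg, grid)
    wl, height = absorption.peak()
    print(f"{dinuc} ({model.name}): absorption maximum {wl:.0f} nm, height {height:.3f}")

ga = cd.reference_model("GA")
cd_spec = cd.cd_spectrum(ga, cfg, grid)
print(f"GA CD at 270 nm: {cd_spec.values[grid.wavelengths_nm == 270.0][0]:+.2f} (negative lobe)")
print(f"GA CD at 250 nm: {cd_spec.values[grid.wavelengths_nm == 250.0][0]:+.2f} (positive lobe)")

# The AG bands sit blue of GA and are more intense; the GA CD shows a
# negative then a positive lobe coming from long wavelengths - the
# signatures that identify the dominant stacking geometry of each system.
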