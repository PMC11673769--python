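"""Packaged reference configurations for the two dinucleotides.

Each profile reproduces the published study conditions for one system:

* AG — dominant *anti-syn* conformer; short DAS lifetime 4.5 ps
  (min-pipi*G(La)), CT recombination lifetime 112 ps, CT formation yield
  0.18.
* GA — dominant *anti-anti* conformer; short DAS lifetime 2.7 ps,
  CT lifetime 170 ps, yield 0.32.

Common constants: 266 nm pump, ~30 fs instrument response, 1 mm path,
8e-6 mol/L absorbed photons, radical-pair molar absorption 1230
mol^-1 L cm^-1, Franck-Condon -> minimum relaxation time constant 100 fs.

The kinetic scheme is a branched cascade: each FC state (initial weight
from its excitation probability at the pump) relaxes to its target
excited-state minimum, and each minimum decays to the ground state with
its lifetime.  The CT species spectrum is scaled so that the zero-time
amplitude of the CT band equals yield x epsilon x l x c_abs — i.e. the
profile's yield is the quantity a correct extraction chain must recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .electronic_structure import ConformerModel, load_conformer_model
from .kinetics import (
    GROUND,
    KineticScheme,
    NoiseModel,
    TASMatrix,
    default_times,
    synthesize_tas,
)
from .spectra import (
    BroadeningConfig,
    SpectralGrid,
    Spectrum,
    esa_spectrum,
    fc_weights_at_pump,
    probe_grid,
    scaled_to_peak,
)

__all__ = [
    "ReferenceProfile",
    "PROFILES",
    "reference_model",
    "reference_scheme",
    "reference_tas",
    "packaged_manifest_path",
]


@dataclass(frozen=True)
class ReferenceProfile:
    """Study-condition constants for one dinucleotide."""

    dinucleotide: str
    conformer: str
    tau_short_ps: float  # min-pipi*G(La) lifetime
    tau_ct_ps: float  # CT recombination lifetime
    tau_npi_ps: float  # min-npi*A lifetime (minor channel)
    phi_ct: float  # CT formation quantum yield
    relax_ps: float = 0.1  # FC -> minimum relaxation
    pump_nm: float = 266.0
    irf_fwhm_fs: float = 30.0
    path_cm: float = 0.1
    c_abs_molar: float = 8e-6
    epsilon_ct_m1cm1: float = 1230.0
    epsilon_pipi_peak: float = 2000.0  # molar scale of the min-pipi*G(La) band
    epsilon_npi_peak: float = 1500.0
    epsilon_fc_peak: float = 1500.0  # FC-state bands; keeps peak |DA| < 1e-3
    band_nm: tuple[float, float] = (500.0, 645.0)


PROFILES: dict[str, ReferenceProfile] = {
    "AG": ReferenceProfile(
        dinucleotide="AG", conformer="anti-syn",
        tau_short_ps=4.5, tau_ct_ps=112.0, tau_npi_ps=1.4, phi_ct=0.18,
    ),
    "GA": ReferenceProfile(
        dinucleotide="GA", conformer="anti-anti",
        tau_short_ps=2.7, tau_ct_ps=170.0, tau_npi_ps=1.4, phi_ct=0.32,
    ),
}

_MANIFESTS = {
    ("AG", "anti-syn"): "ag_anti_syn.json",
    ("AG", "anti-anti"): "ag_anti_anti.json",
    ("GA", "anti-anti"): "ga_anti_anti.json",
}

_MIN_LIFETIME_KEY = {
    "min-pipi*G(La)": "tau_short_ps",
    "min-CT": "tau_ct_ps",
    "min-npi*A": "tau_npi_ps",
    "min-exciton": "tau_short_ps",
}


def packaged_manifest_path(dinucleotide: str, conformer: str | None = None) -> Path:
    """Filesystem path of a packaged conformer manifest."""
    if conformer is None:
        conformer = PROFILES[dinucleotide].conformer
    try:
        fname = _MANIFESTS[(dinucleotide, conformer)]
    except KeyError:
        raise KeyError(f"no packaged model for {dinucleotide} {conformer}") from None
    return Path(resources.files("ctdinuc.data") / fname)


def reference_model(dinucleotide: str, conformer: str | None = None) -> ConformerModel:
    """Load the packaged conformer model of the dominant (or named) conformer."""
    return load_conformer_model(packaged_manifest_path(dinucleotide, conformer))


def reference_scheme(
    dinucleotide: str,
    cfg: BroadeningConfig = BroadeningConfig(),
    grid: SpectralGrid | None = None,
    phi_ct: float | None = None,
) -> tuple[KineticScheme, dict[str, Spectrum], ReferenceProfile]:
    """Build the default kinetic scheme and molar species spectra.

    Returns (scheme, species spectra keyed by compartment, profile).  The
    CT spectrum's band peak is set to phi_ct * epsilon / (CT branching
    fraction) so that the zero-time CT-band amplitude of the synthesized
    matrix is phi_ct * epsilon * l * c_abs.
    """
    profile = PROFILES[dinucleotide]
    if phi_ct is None:
        phi_ct = profile.phi_ct
    if grid is None:
        grid = probe_grid()
    model = reference_model(dinucleotide)

    weights = fc_weights_at_pump(model, cfg, profile.pump_nm)
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no FC state is excited at the pump wavelength")
    init = {label: w / total for label, w in weights.items()}

    minima_labels = sorted({t.target_minimum for t in model.transitions} - {"none"})
    compartments = [t.label for t in model.transitions] + minima_labels + [GROUND]
    n = len(compartments)
    k = np.zeros((n, n))
    idx = {c: i for i, c in enumerate(compartments)}
    k_relax = 1.0 / profile.relax_ps
    for t in model.transitions:
        i = idx[t.label]
        if t.target_minimum != "none":
            k[idx[t.target_minimum], i] += k_relax
            k[i, i] -= k_relax
        else:
            k[idx[GROUND], i] += k_relax
            k[i, i] -= k_relax
    for m in minima_labels:
        rate = 1.0 / getattr(profile, _MIN_LIFETIME_KEY[m])
        k[idx[GROUND], idx[m]] += rate
        k[idx[m], idx[m]] -= rate

    w0 = np.zeros(n)
    for label, w in init.items():
        w0[idx[label]] = w
    scheme = KineticScheme(tuple(compartments), k, w0)

    # branching fraction into the CT minimum
    branch_ct = sum(init[t.label] for t in model.transitions if t.target_minimum == "min-CT")

    species: dict[str, Spectrum] = {}
    for t in model.transitions:
        lines = model.esa_for(t.label)
        if lines:
            species[t.label] = scaled_to_peak(
                esa_spectrum(lines, cfg, grid), profile.epsilon_fc_peak
            )
    for m in minima_labels:
        lines = model.esa_for(m)
        if not lines:
            continue
        raw = esa_spectrum(lines, cfg, grid)
        if m == "min-CT":
            if branch_ct <= 0:
                raise ValueError("no FC state feeds the CT minimum")
            peak = phi_ct * profile.epsilon_ct_m1cm1 / branch_ct
            species[m] = scaled_to_peak(raw, peak, band_nm=profile.band_nm)
        elif m == "min-pipi*G(La)":
            species[m] = scaled_to_peak(raw, profile.epsilon_pipi_peak)
        else:
            species[m] = scaled_to_peak(raw, profile.epsilon_npi_peak)
    return scheme, species, profile


def reference_tas(
    dinucleotide: str,
    noise_sigma: float = 0.0,
    seed: int = 0,
    times_ps: np.ndarray | None = None,
    grid: SpectralGrid | None = None,
    cfg: BroadeningConfig = BroadeningConfig(),
    phi_ct: float | None = None,
) -> TASMatrix:
    """Synthesize the default reference TAS matrix for one dinucleotide."""
    scheme, species, profile = reference_scheme(dinucleotide, cfg, grid, phi_ct)
    return synthesize_tas(
        scheme,
        species,
        irf_fwhm_fs=profile.irf_fwhm_fs,
        noise=NoiseModel(sigma_da=noise_sigma, seed=seed) if noise_sigma > 0 else None,
        grid=grid,
        times_ps=default_times() if times_ps is None else times_ps,
        path_cm=profile.path_cm,
        c_abs_molar=profile.c_abs_molar,
        pump_nm=profile.pump_nm,
    )
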