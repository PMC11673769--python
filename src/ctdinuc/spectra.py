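"""Gaussian broadening of stick spectra and derived steady-state / ESA spectra.

Computed vertical transitions are turned into smooth spectra by (i) shifting
every transition energy by a fixed empirical calibration (default -0.65 eV,
chosen so the lowest bright state of dG matches experiment) and (ii) dressing
each shifted stick with a unit-area Gaussian of fixed FWHM (default 0.4 eV)
in the *energy* domain.  The result is sampled on a wavelength grid; no
|dE/dλ| Jacobian is applied by default, matching how stick-convolved spectra
are conventionally presented against experiment in nm (a toggle exists).

The same machinery serves ground-state absorption (weights = oscillator
strengths), circular dichroism (weights = rotatory strengths, signed) and
excited-state absorption (weights from excited-state transition dipoles).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import FWHM_TO_SIGMA, NM_EV, nm_to_ev
from .electronic_structure import ConformerModel, EsaLine, osc_strength_from_dipole

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "BroadeningConfig",
    "steady_state_grid",
    "probe_grid",
    "broaden",
    "absorption_spectrum",
    "cd_spectrum",
    "esa_spectrum",
    "fc_weights_at_pump",
    "weighted_fc_tas",
    "thermal_difference",
    "scaled_to_peak",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength axis (nm) with an implied energy axis."""

    wavelengths_nm: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-d array")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def energies_ev(self) -> np.ndarray:
        return NM_EV / self.wavelengths_nm

    def __len__(self):
        return self.wavelengths_nm.size

    def __eq__(self, other):
        return isinstance(other, SpectralGrid) and np.array_equal(
            self.wavelengths_nm, other.wavelengths_nm
        )


def steady_state_grid() -> SpectralGrid:
    """Default UV grid for absorption/CD: 200-350 nm at 0.5 nm."""
    return SpectralGrid(np.arange(200.0, 350.0 + 0.25, 0.5))


def probe_grid() -> SpectralGrid:
    """Default transient-absorption probe grid: 330-650 nm at 1 nm."""
    return SpectralGrid(np.arange(330.0, 650.0 + 0.5, 1.0))


@dataclass(frozen=True)
class Spectrum:
    """Intensity sampled on a wavelength grid.

    ``kind`` records what the values mean: molar absorption ('absorption',
    'esa'), signed CD in arbitrary units ('cd') or a relative difference
    ('difference').
    """

    grid: SpectralGrid
    values: np.ndarray
    kind: str = "absorption"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != self.grid.wavelengths_nm.shape:
            raise ValueError("values and grid have different lengths")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")

    def peak(self, band_nm: tuple[float, float] | None = None) -> tuple[float, float]:
        """(wavelength, value) of the maximum, optionally within a band."""
        wl = self.grid.wavelengths_nm
        mask = np.ones_like(wl, dtype=bool)
        if band_nm is not None:
            mask = (wl >= band_nm[0]) & (wl <= band_nm[1])
            if not mask.any():
                raise ValueError(f"band {band_nm} outside grid")
        idx = np.flatnonzero(mask)[np.argmax(self.values[mask])]
        return float(wl[idx]), float(self.values[idx])


@dataclass(frozen=True)
class BroadeningConfig:
    """Gaussian broadening width and calibration shift, both in eV."""

    fwhm_ev: float = 0.4
    shift_ev: float = -0.65
    #: multiply by dE/dλ when sampling on the wavelength grid
    jacobian: bool = False

    def __post_init__(self):
        if self.fwhm_ev <= 0:
            raise ValueError(f"fwhm_ev must be > 0, got {self.fwhm_ev}")

    @property
    def sigma_ev(self) -> float:
        return self.fwhm_ev * FWHM_TO_SIGMA


def _gauss(e: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Unit-area Gaussian in the energy domain (per eV)."""
    return np.exp(-0.5 * ((e - center) / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))


def broaden(
    sticks: Iterable[tuple[float, float]],
    cfg: BroadeningConfig = BroadeningConfig(),
    grid: SpectralGrid | None = None,
    kind: str = "absorption",
) -> Spectrum:
    """Sum of shifted, Gaussian-broadened sticks sampled on the grid.

    Each ``(energy_ev, weight)`` stick contributes
    ``weight * g(E - (energy_ev + shift))`` with ``g`` a unit-area Gaussian
    of sigma ``fwhm/sqrt(8 ln 2)``, so the integral over energy of each band
    equals its stick weight.
    """
    if grid is None:
        grid = steady_state_grid()
    sticks = list(sticks)
    if not sticks:
        raise ValueError("stick list is empty")
    e = grid.energies_ev
    values = np.zeros_like(e)
    for energy_ev, weight in sticks:
        values += weight * _gauss(e, energy_ev + cfg.shift_ev, cfg.sigma_ev)
    if cfg.jacobian:
        values *= e**2 / NM_EV  # dE/dλ in eV per nm
    return Spectrum(grid=grid, values=values, kind=kind)


def absorption_spectrum(
    model: ConformerModel,
    cfg: BroadeningConfig = BroadeningConfig(),
    grid: SpectralGrid | None = None,
) -> Spectrum:
    """Steady-state absorption: transitions weighted by oscillator strength."""
    return broaden(
        [(t.energy_ev, t.osc_strength) for t in model.transitions], cfg, grid, kind="absorption"
    )


def cd_spectrum(
    model: ConformerModel,
    cfg: BroadeningConfig = BroadeningConfig(),
    grid: SpectralGrid | None = None,
) -> Spectrum:
    """Circular dichroism: transitions weighted by (signed) rotatory strength."""
    return broaden(
        [(t.energy_ev, t.rotatory_strength) for t in model.transitions], cfg, grid, kind="cd"
    )


def esa_spectrum(
    state_lines: Sequence[EsaLine],
    cfg: BroadeningConfig = BroadeningConfig(),
    grid: SpectralGrid | None = None,
) -> Spectrum:
    """Excited-state absorption of one state from its ESA lines.

    Dipoles are converted to oscillator strengths and broadened with the
    same shift and FWHM as the steady-state spectra.  An empty line list
    yields an all-zero spectrum (a dark state is not an error).
    """
    if grid is None:
        grid = probe_grid()
    if not state_lines:
        return Spectrum(grid=grid, values=np.zeros(len(grid)), kind="esa")
    sticks = [
        (line.delta_e_ev, osc_strength_from_dipole(line.delta_e_ev, line.dipole_sq_au))
        for line in state_lines
    ]
    return broaden(sticks, cfg, grid, kind="esa")


def fc_weights_at_pump(
    model: ConformerModel,
    cfg: BroadeningConfig = BroadeningConfig(),
    pump_nm: float = 266.0,
    laser_fwhm_nm: float | None = None,
) -> dict[str, float]:
    """Excitation probability of each FC state at the pump wavelength.

    Default: value at the pump energy of each transition's broadened band,
    i.e. oscillator strength times a unit-area Gaussian evaluated at
    E_pump - (E_i + shift).  If ``laser_fwhm_nm`` is given the band is
    instead overlapped with a Gaussian laser spectrum of that FWHM centred
    at the pump (optional refinement, off by default).
    """
    e_pump = nm_to_ev(pump_nm)
    weights: dict[str, float] = {}
    if laser_fwhm_nm is None:
        for t in model.transitions:
            weights[t.label] = t.osc_strength * float(
                _gauss(np.array([e_pump]), t.energy_ev + cfg.shift_ev, cfg.sigma_ev)[0]
            )
    else:
        # overlap integral of two Gaussians is a Gaussian with summed variances
        half = 0.5 * laser_fwhm_nm
        sigma_laser_ev = (nm_to_ev(pump_nm - half) - nm_to_ev(pump_nm + half)) / 2 * FWHM_TO_SIGMA * 2
        sigma = math.sqrt(cfg.sigma_ev**2 + sigma_laser_ev**2)
        for t in model.transitions:
            weights[t.label] = t.osc_strength * float(
                _gauss(np.array([e_pump]), t.energy_ev + cfg.shift_ev, sigma)[0]
            )
    return weights


def weighted_fc_tas(
    model: ConformerModel,
    cfg: BroadeningConfig = BroadeningConfig(),
    pump_nm: float = 266.0,
    grid: SpectralGrid | None = None,
) -> Spectrum:
    """Pump-weighted superposition of the FC states' ESA spectra.

    Emulates the transient spectrum immediately after excitation: each FC
    state's ESA spectrum is scaled by its probability of being populated by
    the pump pulse.
    """
    if grid is None:
        grid = probe_grid()
    weights = fc_weights_at_pump(model, cfg, pump_nm)
    total = np.zeros(len(grid))
    for t in model.transitions:
        lines = model.esa_for(t.label)
        if lines:
            total += weights[t.label] * esa_spectrum(lines, cfg, grid).values
    return Spectrum(grid=grid, values=total, kind="esa")


def thermal_difference(
    spec_hot: Spectrum,
    spec_cold: Spectrum,
    band_nm_min: float = 255.0,
) -> tuple[Spectrum, float]:
    """Relative high/low-temperature difference and its plateau value.

    Returns ``(A_hot - A_cold)/A_cold`` pointwise plus the maximum of that
    ratio (x100, percent) over wavelengths above ``band_nm_min`` — the
    hypochromism the stacked dinucleotide shows at room temperature.
    Points where the cold spectrum vanishes are excluded with a warning.
    """
    if spec_hot.grid != spec_cold.grid:
        raise ValueError("hot and cold spectra are on different grids")
    cold = spec_cold.values
    hot = spec_hot.values
    valid = cold != 0.0
    if not valid.all():
        warnings.warn(
            f"{np.count_nonzero(~valid)} grid points with zero cold absorbance excluded",
            stacklevel=2,
        )
    diff = np.zeros_like(cold)
    diff[valid] = (hot[valid] - cold[valid]) / cold[valid]
    wl = spec_hot.grid.wavelengths_nm
    band = valid & (wl > band_nm_min)
    if not band.any():
        raise ValueError(f"no usable grid points above {band_nm_min} nm")
    percent = float(np.max(diff[band]) * 100.0)
    return Spectrum(grid=spec_hot.grid, values=diff, kind="difference"), percent


def scaled_to_peak(
    spectrum: Spectrum, peak_value: float, band_nm: tuple[float, float] | None = None
) -> Spectrum:
    """Rescale a spectrum so its maximum (optionally within a band) equals
    ``peak_value``; used to give shape-only ESA spectra absolute molar units."""
    _, current = spectrum.peak(band_nm)
    if current == 0:
        raise ValueError("cannot scale an all-zero spectrum")
    return Spectrum(
        grid=spectrum.grid, values=spectrum.values * (peak_value / current), kind=spectrum.kind
    )
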