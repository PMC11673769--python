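"""First-order kinetic schemes and synthetic transient-absorption matrices.

The photophysics being emulated: a 266 nm pump populates several
Franck-Condon states of a stacked dinucleotide; within ~100 fs each relaxes
to its excited-state minimum (charge-transfer, pipi*G(La) or npi*A); the
minima then decay to the ground state on the ps scale (charge recombination
for the CT state).  The populations obey first-order kinetics dc/dt = K c
and the observed differential absorbance is the population-weighted sum of
the species' molar ESA spectra times path length and excited concentration,
convolved in time with a Gaussian instrument response (~30 fs FWHM
pump-probe cross-correlation), plus Gaussian detection noise.

Populations are propagated by the matrix exponential; the instrument-
response convolution of each exponential eigenmode is done in closed form
(exp x Gauss -> scaled complementary error function), so the simulator is
exact to machine precision rather than grid-limited.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import eig, expm
from scipy.special import erfc, erfcx

from .constants import FWHM_TO_SIGMA
from .spectra import SpectralGrid, Spectrum

__all__ = [
    "KineticScheme",
    "TASMatrix",
    "NoiseModel",
    "propagate",
    "synthesize_tas",
    "magic_angle",
    "synthesize_melting_pair",
    "default_times",
]

GROUND = "ground"


@dataclass(frozen=True)
class KineticScheme:
    """Compartmental first-order scheme with a population-conserving rate matrix.

    ``rate_matrix[i, j]`` (i != j) is the rate constant (ps^-1) of the
    j -> i transfer; diagonals hold minus the total outflow of each
    compartment, so columns sum to zero and total population is conserved
    (the ground compartment is explicit and absorbing).
    ``initial_weights`` is the population injected at time zero (sums to 1).
    """

    compartments: tuple[str, ...]
    rate_matrix: np.ndarray
    initial_weights: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.rate_matrix, dtype=float)
        w = np.asarray(self.initial_weights, dtype=float)
        object.__setattr__(self, "rate_matrix", k)
        object.__setattr__(self, "initial_weights", w)
        n = len(self.compartments)
        if k.shape != (n, n):
            raise ValueError(f"rate matrix must be {n}x{n}")
        off = k.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        colsums = k.sum(axis=0)
        if np.max(np.abs(colsums)) > 1e-10:
            raise ValueError(
                f"rate matrix is not population-conserving (column sums {colsums})"
            )
        if w.shape != (n,):
            raise ValueError("initial_weights length mismatch")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-10:
            raise ValueError("initial weights must be >= 0 and sum to 1")

    def index(self, label: str) -> int:
        return self.compartments.index(label)


@dataclass(frozen=True)
class NoiseModel:
    """Additive homoscedastic Gaussian noise on the differential absorbance."""

    sigma_da: float = 1e-5
    seed: int = 0

    def __post_init__(self):
        if self.sigma_da < 0:
            raise ValueError("sigma_da must be >= 0")


@dataclass(frozen=True)
class TASMatrix:
    """Time x wavelength differential absorbance with acquisition metadata."""

    times_ps: np.ndarray
    wavelengths_nm: np.ndarray
    da: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times_ps, dtype=float)
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        da = np.asarray(self.da, dtype=float)
        object.__setattr__(self, "times_ps", t)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "da", da)
        if np.any(np.diff(t) <= 0) or np.any(np.diff(wl) <= 0):
            raise ValueError("time and wavelength axes must be strictly increasing")
        if da.shape != (t.size, wl.size):
            raise ValueError(f"da must be {t.size}x{wl.size}, got {da.shape}")
        if not np.all(np.isfinite(da)):
            raise ValueError("differential absorbance must be finite")
        if np.max(np.abs(da)) >= 1e-2:
            warnings.warn(
                "``|DA|`` exceeds 1e-2 OD; measured transient signals stay below 1e-3",
                stacklevel=2,
            )

    def spectrum_at(self, t_ps: float) -> np.ndarray:
        """DA spectrum at the time point nearest ``t_ps``."""
        idx = int(np.argmin(np.abs(self.times_ps - t_ps)))
        return self.da[idx]

    def window(self, t_min_ps: float, t_max_ps: float) -> "TASMatrix":
        mask = (self.times_ps >= t_min_ps) & (self.times_ps <= t_max_ps)
        if not mask.any():
            raise ValueError(f"no time points in window [{t_min_ps}, {t_max_ps}] ps")
        return TASMatrix(self.times_ps[mask], self.wavelengths_nm, self.da[mask], dict(self.meta))


def propagate(scheme: KineticScheme, times_ps: Sequence[float]) -> np.ndarray:
    """Solve dc/dt = K c for the scheme; returns populations (n_times, n_comp).

    Uses the matrix exponential at every requested (non-negative) time.
    """
    t = np.asarray(times_ps, dtype=float)
    if np.any(t < 0):
        raise ValueError("propagate expects non-negative times")
    out = np.empty((t.size, len(scheme.compartments)))
    for i, ti in enumerate(t):
        out[i] = expm(scheme.rate_matrix * ti) @ scheme.initial_weights
    return out


def _exp_gauss(t: np.ndarray, rate: float, sigma: float) -> np.ndarray:
    """theta(t) exp(-rate*t) convolved with a unit-area Gaussian of width sigma.

    Closed form 0.5 exp((rate*sigma)^2/2 - rate*t) erfc((rate*sigma^2 - t)/(sigma sqrt2)),
    evaluated through erfcx where the plain form would overflow.
    """
    if sigma == 0.0:
        return np.where(t >= 0, np.exp(-rate * np.clip(t, 0, None)), 0.0)
    u = (rate * sigma**2 - t) / (sigma * math.sqrt(2.0))
    out = np.empty_like(t)
    pos = u >= 0
    # erfcx(u) e^{-t^2/(2 sigma^2)} == e^{c} erfc(u) with c = (rate sigma)^2/2 - rate t
    out[pos] = 0.5 * erfcx(u[pos]) * np.exp(-0.5 * (t[pos] / sigma) ** 2)
    c = 0.5 * (rate * sigma) ** 2 - rate * t[~pos]
    out[~pos] = 0.5 * np.exp(c) * erfc(u[~pos])
    return out


def _eigenmodes(scheme: KineticScheme) -> tuple[np.ndarray, np.ndarray]:
    """Decompose populations into exponential modes: c(t) = B @ exp(lam t)."""
    lam, v = eig(scheme.rate_matrix)
    coeff = np.linalg.solve(v, scheme.initial_weights.astype(complex))
    b = v * coeff[np.newaxis, :]  # (n_comp, n_modes)
    return lam, b


def synthesize_tas(
    scheme: KineticScheme,
    species_spectra: Mapping[str, Spectrum],
    irf_fwhm_fs: float = 30.0,
    noise: NoiseModel | None = None,
    grid: SpectralGrid | None = None,
    times_ps: Sequence[float] | None = None,
    path_cm: float = 0.1,
    c_abs_molar: float = 8e-6,
    pump_nm: float = 266.0,
    gsb: Spectrum | None = None,
) -> TASMatrix:
    """Forward-model a differential-absorbance matrix from a kinetic scheme.

    DA(t, λ) = sum_k [c_k ⊛ IRF](t) ε_k(λ) l c_abs (+ noise), where ε_k is
    the molar ESA spectrum of compartment k (compartments without a spectrum
    contribute nothing).  If ``gsb`` is given, a ground-state-bleach term
    -(total excited population)(t) x gsb(λ) l c_abs is added (off by
    default: the computed transient spectra are ESA-only).
    """
    if times_ps is None:
        times_ps = default_times()
    t = np.asarray(times_ps, dtype=float)
    spectra = dict(species_spectra)
    if grid is None:
        grid = next(iter(spectra.values())).grid if spectra else None
    if grid is None:
        raise ValueError("no grid available")
    for label, spec in spectra.items():
        if spec.grid != grid:
            raise ValueError(f"species spectrum {label!r} is not on the common grid")
        if label != GROUND and label not in scheme.compartments:
            raise ValueError(f"species spectrum {label!r} names no compartment")

    sigma_t = irf_fwhm_fs * 1e-3 * FWHM_TO_SIGMA  # ps
    lam, b = _eigenmodes(scheme)
    # IRF-convolved population of every compartment, mode by mode
    conv = np.zeros((t.size, len(scheme.compartments)))
    for m, lam_m in enumerate(lam):
        if abs(lam_m.imag) > 1e-12:
            raise ValueError("oscillatory eigenmode in a first-order decay scheme")
        profile = _exp_gauss(t, -lam_m.real, sigma_t)
        conv += np.real(np.outer(profile, b[:, m]))

    da = np.zeros((t.size, len(grid)))
    for label, spec in spectra.items():
        if label == GROUND:
            continue
        k = scheme.index(label)
        da += np.outer(conv[:, k], spec.values) * path_cm * c_abs_molar
    if gsb is not None:
        excited = np.zeros(t.size)
        for k, label in enumerate(scheme.compartments):
            if label != GROUND:
                excited += conv[:, k]
        da -= np.outer(excited, gsb.values) * path_cm * c_abs_molar

    meta = {
        "pump_nm": pump_nm,
        "irf_fwhm_fs": irf_fwhm_fs,
        "path_length_cm": path_cm,
        "absorbed_photon_conc_molar": c_abs_molar,
        "seed": None,
        "noise_sigma_da": 0.0,
    }
    if noise is not None and noise.sigma_da > 0:
        rng = np.random.default_rng(noise.seed)
        da = da + rng.normal(0.0, noise.sigma_da, size=da.shape)
        meta["seed"] = noise.seed
        meta["noise_sigma_da"] = noise.sigma_da
    return TASMatrix(times_ps=t, wavelengths_nm=grid.wavelengths_nm, da=da, meta=meta)


def magic_angle() -> float:
    """Pump-probe polarization angle (degrees) cancelling rotational
    anisotropy: arccos(1/sqrt 3) = 54.7356..."""
    return math.degrees(math.acos(1.0 / math.sqrt(3.0)))


def synthesize_melting_pair(
    monomer_spectrum: Spectrum,
    hypochromism_fraction: float,
    crossover_nm: float = 255.0,
) -> tuple[Spectrum, Spectrum]:
    """Two-state stacking transform: build a (cold, hot) absorption pair.

    The hot (unstacked, high-temperature) spectrum is the monomer sum
    itself.  The cold (stacked) spectrum is depressed above the crossover
    so that (A_hot - A_cold)/A_cold equals ``hypochromism_fraction`` there,
    and uniformly enhanced below it so the integrated intensity is
    conserved — hypochromism above the crossover, hyperchromism below, as
    base stacking produces.
    """
    if not 0.0 <= hypochromism_fraction < 1.0:
        raise ValueError("hypochromism_fraction must lie in [0, 1)")
    hot = monomer_spectrum
    wl = hot.grid.wavelengths_nm
    above = wl > crossover_nm
    cold = hot.values.copy()
    cold[above] = hot.values[above] / (1.0 + hypochromism_fraction)
    area_hot = np.trapezoid(hot.values, wl)
    area_above_cold = np.trapezoid(np.where(above, cold, 0.0), wl)
    area_below_hot = np.trapezoid(np.where(above, 0.0, hot.values), wl)
    if hypochromism_fraction > 0 and area_below_hot > 0:
        # conserve total area: what the hypochromic band lost, the
        # short-wavelength side gains (hyperchromism)
        cold[~above] = hot.values[~above] * ((area_hot - area_above_cold) / area_below_hot)
    spec_cold = Spectrum(grid=hot.grid, values=cold, kind="absorption")
    return spec_cold, hot


def default_times() -> np.ndarray:
    """Default delay axis: dense femtosecond sampling through the pump,
    then quasi-logarithmic coverage out to 450 ps."""
    early = np.arange(-0.3, 2.0, 0.02)
    late = np.geomspace(2.0, 450.0, 140)
    return np.unique(np.concatenate([early, late]))
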