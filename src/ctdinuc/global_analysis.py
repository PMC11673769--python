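"""Global multi-exponential fitting of transient-absorption matrices.

All probe wavelengths are fitted simultaneously with a shared set of
exponential time constants; the wavelength-dependent amplitudes attached to
each lifetime form the decay-associated spectra (DAS).  The fit is windowed
to late delays (default 4-45 ps) where every excited-state minimum has been
reached, so plain exponentials are adequate and no instrument-response
convolution enters the model.

The optimisation uses variable projection: for any trial lifetimes the
amplitudes are the solution of a linear least-squares problem per
wavelength, so only the lifetimes (log-parameterised to stay positive) are
searched nonlinearly.  Any subset of lifetimes may be held fixed, e.g. to a
charge-recombination time known from an independent measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .kinetics import TASMatrix

__all__ = ["DASResult", "FitDiagnostics", "DegenerateDataError", "fit_das", "fit_quality"]


class DegenerateDataError(ValueError):
    """The data cannot support the requested number of exponentials."""


@dataclass(frozen=True)
class DASResult:
    """Lifetimes (ascending) and decay-associated amplitude spectra."""

    lifetimes_ps: np.ndarray
    fixed_mask: np.ndarray
    das: np.ndarray  # (n_exp, n_wavelengths)
    wavelengths_nm: np.ndarray
    window_ps: tuple[float, float]
    residual_rms: float
    n_iterations: int

    def __post_init__(self):
        tau = np.asarray(self.lifetimes_ps, dtype=float)
        object.__setattr__(self, "lifetimes_ps", tau)
        object.__setattr__(self, "fixed_mask", np.asarray(self.fixed_mask, dtype=bool))
        object.__setattr__(self, "das", np.asarray(self.das, dtype=float))
        object.__setattr__(self, "wavelengths_nm", np.asarray(self.wavelengths_nm, dtype=float))
        if np.any(tau <= 0):
            raise ValueError("lifetimes must be positive")
        if self.das.shape != (tau.size, self.wavelengths_nm.size):
            raise ValueError("das shape mismatch")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


@dataclass(frozen=True)
class FitDiagnostics:
    """Residual summary of a DAS fit plus an information criterion."""

    residuals: np.ndarray  # (n_times, n_wavelengths), data - model
    residual_rms: float
    per_wavelength_rms: np.ndarray
    aic: float
    n_parameters: int


def _design(times: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.exp(-times[:, None] / taus[None, :])


def _solve_amplitudes(e: np.ndarray, data: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(e, data, rcond=None)[0]


def fit_das(
    tas: TASMatrix,
    n_exp: int,
    fixed: Mapping[int, float] | None = None,
    window_ps: tuple[float, float] = (4.0, 45.0),
    rank_rtol: float = 1e-10,
    max_nfev: int = 500,
) -> DASResult:
    """Windowed global multi-exponential fit by variable projection.

    ``fixed`` maps lifetime indices (after ascending sort of the fixed
    values among themselves) to values in ps that are not optimised.
    Free lifetimes are started from three spreads of a log-spaced ladder
    across the window and the best optimum is kept, making the fit
    deterministic for given data.

    Raises :class:`DegenerateDataError` when the windowed matrix has
    numerical rank below ``n_exp`` (e.g. two exponentials requested for a
    rank-one, single-exponential matrix).
    """
    if n_exp < 1:
        raise ValueError("n_exp must be >= 1")
    fixed = dict(fixed or {})
    for idx, val in fixed.items():
        if not 0 <= idx < n_exp:
            raise ValueError(f"fixed index {idx} outside 0..{n_exp - 1}")
        if val <= 0:
            raise ValueError("fixed lifetimes must be positive")

    windowed = tas.window(*window_ps)
    times = windowed.times_ps
    data = windowed.da
    if times.size < n_exp + 1:
        raise ValueError("window holds fewer time points than parameters")

    sv = np.linalg.svd(data, compute_uv=False)
    eff_rank = int(np.count_nonzero(sv > rank_rtol * sv[0]))
    if eff_rank < n_exp:
        raise DegenerateDataError(
            f"data support only {eff_rank} exponential component(s) "
            f"(singular values {sv[: n_exp + 1].tolist()}); reduce n_exp"
        )

    free_idx = [k for k in range(n_exp) if k not in fixed]
    tau_full = np.empty(n_exp)
    for idx, val in fixed.items():
        tau_full[idx] = val

    def residual(log_tau_free: np.ndarray) -> np.ndarray:
        tau = tau_full.copy()
        tau[free_idx] = np.exp(log_tau_free)
        e = _design(times, tau)
        amps = _solve_amplitudes(e, data)
        return (e @ amps - data).ravel()

    if free_idx:
        ladder = np.geomspace(window_ps[0], window_ps[1], len(free_idx) + 2)[1:-1]
        best = None
        nfev = 0
        for factor in (0.3, 1.0, 3.0):
            start = np.log(ladder * factor)
            sol = least_squares(
                residual, start, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=max_nfev,
            )
            nfev += sol.nfev
            if best is None or sol.cost < best.cost:
                best = sol
        tau_full[free_idx] = np.exp(best.x)
        n_iterations = nfev
    else:
        n_iterations = 0

    e = _design(times, tau_full)
    cond = np.linalg.cond(e)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateDataError(
            f"exponential design matrix is singular at the optimum "
            f"(condition number {cond:.3g}); lifetimes {tau_full.tolist()}"
        )
    amps = _solve_amplitudes(e, data)
    sse = float(np.sum((e @ amps - data) ** 2))

    order = np.argsort(tau_full, kind="stable")
    fixed_mask = np.array([k in fixed for k in range(n_exp)])
    return DASResult(
        lifetimes_ps=tau_full[order],
        fixed_mask=fixed_mask[order],
        das=amps[order],
        wavelengths_nm=windowed.wavelengths_nm,
        window_ps=window_ps,
        residual_rms=math.sqrt(sse / data.size),
        n_iterations=n_iterations,
    )


def fit_quality(result: DASResult, tas: TASMatrix) -> FitDiagnostics:
    """Residual traces and an AIC for comparing fits across ``n_exp``.

    AIC = N ln(SSE/N) + 2p with p counting the free lifetimes plus all
    amplitudes; lower is better.
    """
    windowed = tas.window(*result.window_ps)
    e = _design(windowed.times_ps, result.lifetimes_ps)
    model = e @ result.das
    residuals = windowed.da - model
    sse = float(np.sum(residuals**2))
    n = residuals.size
    n_free_tau = int(np.count_nonzero(~result.fixed_mask))
    p = n_free_tau + result.das.size
    aic = n * math.log(max(sse, 1e-300) / n) + 2 * p
    return FitDiagnostics(
        residuals=residuals,
        residual_rms=math.sqrt(sse / n),
        per_wavelength_rms=np.sqrt(np.mean(residuals**2, axis=0)),
        aic=aic,
        n_parameters=p,
    )
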