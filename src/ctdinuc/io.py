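"""Plain-text readers and writers for spectra, TAS matrices and fit results.

Formats:

* Spectrum CSV — two columns ``wavelength_nm,value``.
* TAS CSV — first row the wavelength axis (corner cell ``time_ps``),
  first column the delay axis, body the differential absorbance; a JSON
  sidecar ``<name>.meta.json`` carries acquisition metadata.
* DAS — JSON summary plus a CSV ``wavelength_nm,das_tau1,das_tau2,...``.
* Yield report — flat JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .global_analysis import DASResult
from .kinetics import TASMatrix
from .quantum_yield import YieldReport
from .spectra import SpectralGrid, Spectrum

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_tas",
    "read_tas",
    "write_das",
    "read_das",
    "write_yield_report",
]


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.grid.wavelengths_nm, "value": spectrum.values}
    ).to_csv(path, index=False)
    return path


def read_spectrum(path: str | Path, kind: str = "absorption") -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(
        grid=SpectralGrid(df["wavelength_nm"].to_numpy()),
        values=df["value"].to_numpy(),
        kind=kind,
    )


def write_tas(tas: TASMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(tas.da, index=tas.times_ps, columns=tas.wavelengths_nm)
    df.index.name = "time_ps"
    df.to_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta_path.write_text(json.dumps(dict(tas.meta), indent=1, sort_keys=True))
    return path


def read_tas(path: str | Path) -> TASMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return TASMatrix(
        times_ps=df.index.to_numpy(dtype=float),
        wavelengths_nm=np.array([float(c) for c in df.columns]),
        da=df.to_numpy(dtype=float),
        meta=meta,
    )


def write_das(result: DASResult, path: str | Path) -> Path:
    """JSON summary at ``path``; amplitude spectra as sibling ``<stem>.csv``."""
    path = Path(path)
    payload = {
        "lifetimes_ps": result.lifetimes_ps.tolist(),
        "fixed_mask": result.fixed_mask.tolist(),
        "window_ps": list(result.window_ps),
        "residual_rms": result.residual_rms,
        "n_iterations": result.n_iterations,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    columns = {"wavelength_nm": result.wavelengths_nm}
    for k, das_k in enumerate(result.das, start=1):
        columns[f"das_tau{k}"] = das_k
    pd.DataFrame(columns).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_das(path: str | Path) -> DASResult:
    path = Path(path)
    payload = json.loads(path.read_text())
    df = pd.read_csv(path.with_suffix(".csv"))
    das = np.vstack(
        [df[c].to_numpy() for c in df.columns if c.startswith("das_tau")]
    )
    return DASResult(
        lifetimes_ps=np.array(payload["lifetimes_ps"]),
        fixed_mask=np.array(payload["fixed_mask"], dtype=bool),
        das=das,
        wavelengths_nm=df["wavelength_nm"].to_numpy(),
        window_ps=tuple(payload["window_ps"]),
        residual_rms=payload["residual_rms"],
        n_iterations=payload["n_iterations"],
    )


def write_yield_report(report: YieldReport, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "phi_ct": report.phi_ct,
        "da_zero": report.da_zero,
        "da_ref": report.da_ref,
        "peak_nm": report.peak_nm,
        "note": report.note,
        "config": asdict(report.config),
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path
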