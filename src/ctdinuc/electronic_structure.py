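"""Tabulated electronic-structure data for stacked dinucleotide conformers.

A :class:`ConformerModel` bundles everything the downstream spectral and
kinetic machinery needs to know about one glycosidic-bond conformer of a
dApdG / dGpdA dinucleotide: its ground-state energy relative to the
*anti-anti* stacking mode, the vertically excited (Franck-Condon)
transitions with oscillator / rotatory strengths and Mulliken
charge-transfer characters, the excited-state minima those transitions
relax to, and the excited-state -> excited-state absorption lines of every
state.  The tables are consumed as plain CSV; nothing here runs or parses
a quantum-chemistry package.

Energies are stored *unshifted* (as computed); the empirical calibration
shift is applied only when a spectrum is built.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .constants import HARTREE_EV, KB_EV_PER_K, ROOM_TEMPERATURE_K

__all__ = [
    "Transition",
    "EsaLine",
    "ConformerModel",
    "PopulationTable",
    "ValidationError",
    "ParseError",
    "load_conformer_model",
    "save_conformer_model",
    "boltzmann_weights",
    "osc_strength_from_dipole",
]

#: Allowed electronic-character labels for a transition.
CHARACTERS = frozenset({"pipi*G(La)", "pipi*A", "npi*A", "CT", "mixed", "exciton"})

#: Allowed relaxation targets (excited-state PES minima) plus "none".
MINIMA = frozenset({"min-CT", "min-pipi*G(La)", "min-npi*A", "min-exciton", "none"})


class ValidationError(ValueError):
    """A physical invariant of a record is violated."""


class ParseError(ValueError):
    """A table row or manifest could not be interpreted."""


@dataclass(frozen=True)
class Transition:
    """One vertical electronic transition (or minimum) of a conformer.

    ``ct_character_au`` is the Mulliken charge difference between excited
    and ground state (0 = locally excited, 1 = full electron transfer).
    """

    label: str
    energy_ev: float
    osc_strength: float
    rotatory_strength: float = 0.0
    ct_character_au: float = 0.0
    character: str = "mixed"
    target_minimum: str = "none"

    def __post_init__(self):
        if not self.energy_ev > 0:
            raise ValidationError(f"{self.label}: energy_ev must be > 0, got {self.energy_ev}")
        if self.osc_strength < 0:
            raise ValidationError(f"{self.label}: osc_strength must be >= 0, got {self.osc_strength}")
        if not 0.0 <= self.ct_character_au <= 1.0:
            raise ValidationError(
                f"{self.label}: ct_character_au must lie in [0, 1], got {self.ct_character_au}"
            )
        if self.character not in CHARACTERS:
            raise ValidationError(f"{self.label}: unknown character {self.character!r}")
        if self.target_minimum not in MINIMA:
            raise ValidationError(f"{self.label}: unknown target_minimum {self.target_minimum!r}")


@dataclass(frozen=True)
class EsaLine:
    """One excited-state -> excited-state absorption line.

    ``delta_e_ev`` is the (unshifted) energy gap probed, ``dipole_sq_au``
    the squared transition dipole between the two excited states.
    """

    from_state: str
    delta_e_ev: float
    dipole_sq_au: float

    def __post_init__(self):
        if not self.delta_e_ev > 0:
            raise ValidationError(f"{self.from_state}: delta_e_ev must be > 0, got {self.delta_e_ev}")
        if self.dipole_sq_au < 0:
            raise ValidationError(f"{self.from_state}: dipole_sq_au must be >= 0, got {self.dipole_sq_au}")


@dataclass(frozen=True)
class ConformerModel:
    """Complete stick-level electronic structure of one conformer."""

    name: str
    dinucleotide: str
    delta_g_ev: float
    transitions: tuple[Transition, ...]
    minima: tuple[Transition, ...] = ()
    esa_lines: tuple[EsaLine, ...] = ()

    def __post_init__(self):
        if self.name not in {"anti-anti", "anti-syn", "syn-anti", "syn-syn"}:
            raise ValidationError(f"unknown conformer name {self.name!r}")
        if self.dinucleotide not in {"AG", "GA"}:
            raise ValidationError(f"dinucleotide must be 'AG' or 'GA', got {self.dinucleotide!r}")
        energies = [t.energy_ev for t in self.transitions]
        if energies != sorted(energies):
            raise ValidationError("transitions must be ordered by increasing energy_ev")
        minimum_labels = {m.label for m in self.minima}
        for t in self.transitions:
            if t.target_minimum != "none" and t.target_minimum not in minimum_labels:
                raise ValidationError(
                    f"{t.label}: target_minimum {t.target_minimum!r} not present in minima"
                )

    def esa_for(self, state_label: str) -> tuple[EsaLine, ...]:
        """ESA lines belonging to one state (FC transition or minimum)."""
        return tuple(line for line in self.esa_lines if line.from_state == state_label)

    def transition(self, label: str) -> Transition:
        for t in self.transitions:
            if t.label == label:
                return t
        for m in self.minima:
            if m.label == label:
                return m
        raise KeyError(label)


@dataclass(frozen=True)
class PopulationTable:
    """Boltzmann weights of conformers; values sum to one."""

    weights: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"population weights sum to {total}, not 1")

    def __getitem__(self, name: str) -> float:
        return self.weights[name]

    def items(self):
        return self.weights.items()


# ---------------------------------------------------------------------------
# table I/O

_STICK_COLUMNS = [
    "label",
    "energy_ev",
    "osc_strength",
    "rotatory_strength",
    "ct_character_au",
    "character",
    "target_minimum",
]
_ESA_COLUMNS = ["from_state", "delta_e_ev", "dipole_sq_au"]


def _read_stick_table(path: Path) -> tuple[Transition, ...]:
    df = pd.read_csv(path)
    missing = set(_STICK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                Transition(
                    label=str(row["label"]),
                    energy_ev=float(row["energy_ev"]),
                    osc_strength=float(row["osc_strength"]),
                    rotatory_strength=float(row["rotatory_strength"]),
                    ct_character_au=float(row["ct_character_au"]),
                    character=str(row["character"]),
                    target_minimum=str(row["target_minimum"]),
                )
            )
        except ValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row {i}: {exc}") from exc
    return tuple(out)


def _read_esa_table(path: Path) -> tuple[EsaLine, ...]:
    df = pd.read_csv(path)
    missing = set(_ESA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                EsaLine(
                    from_state=str(row["from_state"]),
                    delta_e_ev=float(row["delta_e_ev"]),
                    dipole_sq_au=float(row["dipole_sq_au"]),
                )
            )
        except ValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed row {i}: {exc}") from exc
    return tuple(out)


def load_conformer_model(manifest_path: str | Path) -> ConformerModel:
    """Load a conformer from a JSON manifest referencing its CSV tables.

    The manifest carries ``name``, ``dinucleotide``, ``delta_g_ev`` and
    relative paths ``sticks``, ``minima``, ``esa``.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ParseError(f"manifest not found: {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{manifest_path}: invalid JSON: {exc}") from exc
    base = manifest_path.parent
    for key in ("name", "dinucleotide", "delta_g_ev", "sticks"):
        if key not in manifest:
            raise ParseError(f"{manifest_path}: missing manifest key {key!r}")
    transitions = _read_stick_table(base / manifest["sticks"])
    minima = _read_stick_table(base / manifest["minima"]) if manifest.get("minima") else ()
    esa = _read_esa_table(base / manifest["esa"]) if manifest.get("esa") else ()
    return ConformerModel(
        name=manifest["name"],
        dinucleotide=manifest["dinucleotide"],
        delta_g_ev=float(manifest["delta_g_ev"]),
        transitions=transitions,
        minima=minima,
        esa_lines=esa,
    )


def save_conformer_model(model: ConformerModel, directory: str | Path, stem: str) -> Path:
    """Write a conformer back to manifest + CSV tables; returns manifest path.

    Values are written with ``repr`` round-trip precision so that
    load -> save -> load is value-identical.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _sticks_frame(records):
        return pd.DataFrame(
            [
                {
                    "label": t.label,
                    "energy_ev": t.energy_ev,
                    "osc_strength": t.osc_strength,
                    "rotatory_strength": t.rotatory_strength,
                    "ct_character_au": t.ct_character_au,
                    "character": t.character,
                    "target_minimum": t.target_minimum,
                }
                for t in records
            ],
            columns=_STICK_COLUMNS,
        )

    _sticks_frame(model.transitions).to_csv(directory / f"{stem}_sticks.csv", index=False)
    manifest = {
        "name": model.name,
        "dinucleotide": model.dinucleotide,
        "delta_g_ev": model.delta_g_ev,
        "sticks": f"{stem}_sticks.csv",
    }
    if model.minima:
        _sticks_frame(model.minima).to_csv(directory / f"{stem}_minima.csv", index=False)
        manifest["minima"] = f"{stem}_minima.csv"
    if model.esa_lines:
        pd.DataFrame(
            [
                {"from_state": l.from_state, "delta_e_ev": l.delta_e_ev, "dipole_sq_au": l.dipole_sq_au}
                for l in model.esa_lines
            ],
            columns=_ESA_COLUMNS,
        ).to_csv(directory / f"{stem}_esa.csv", index=False)
        manifest["esa"] = f"{stem}_esa.csv"
    manifest_path = directory / f"{stem}.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


# ---------------------------------------------------------------------------
# derived quantities


def boltzmann_weights(
    delta_g_ev: Mapping[str, float] | Sequence[float],
    temperature_k: float = ROOM_TEMPERATURE_K,
) -> PopulationTable:
    """Boltzmann conformer populations from relative ground-state energies.

    weight_i ∝ exp(-ΔG_i / k_B T).  Invariant under a uniform shift of all
    energies; the minimum is subtracted before exponentiation for
    numerical stability.
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature_k must be > 0, got {temperature_k}")
    if isinstance(delta_g_ev, Mapping):
        names = list(delta_g_ev.keys())
        energies = [float(v) for v in delta_g_ev.values()]
    else:
        energies = [float(v) for v in delta_g_ev]
        names = [f"conformer_{i}" for i in range(len(energies))]
    if not energies:
        raise ValueError("delta_g_ev is empty")
    if any(not math.isfinite(e) for e in energies):
        raise ValueError("non-finite relative energy")
    kt = KB_EV_PER_K * temperature_k
    emin = min(energies)
    raw = [math.exp(-(e - emin) / kt) for e in energies]
    total = sum(raw)
    return PopulationTable({n: r / total for n, r in zip(names, raw)})


def osc_strength_from_dipole(delta_e_ev: float, dipole_sq_au: float) -> float:
    """Oscillator strength from a transition energy and squared dipole.

    f = (2/3) * ΔE[hartree] * |μ|²[a.u.]; used to turn excited-state ->
    excited-state dipoles into stick intensities for ESA spectra.
    """
    if delta_e_ev < 0 or dipole_sq_au < 0:
        raise ValueError("delta_e_ev and dipole_sq_au must be >= 0")
    return (2.0 / 3.0) * (delta_e_ev / HARTREE_EV) * dipole_sq_au
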