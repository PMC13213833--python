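"""Readers and writers for every external format the toolkit touches.

Formats:

* XYZ geometries (standard count / comment / ``El x y z`` layout).
* A pinned ORCA-like frequency-output dialect.  The grammar is exactly the
  subset emitted by :func:`microkin.fixtures.make_orca_like_text`:

  - the final electronic energy on a line
    ``FINAL SINGLE POINT ENERGY     <float>`` (the *last* occurrence wins,
    as in an optimization trace);
  - an optional ``VIBRATIONAL FREQUENCIES`` block of lines
    ``  <i>:   <float> cm**-1`` in which imaginary modes appear as negative
    wavenumbers and exact-``0.00`` translational/rotational placeholders are
    dropped;
  - an optional ``CARTESIAN COORDINATES (ANGSTROEM)`` block of
    ``El x y z`` rows terminated by a blank line;
  - an optional ``Multiplicity           Mult  ....  <int>`` line.

  Real ORCA outputs that happen to match this subset parse too, but only the
  fixture-emitted grammar is the contract.
* The mechanism JSON schema (version 1), see :func:`load_mechanism`.
* CSV result tables (UTF-8, '.' decimal, ',' separator).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import (
    MechanismReferenceError,
    MissingEnergyError,
    ParseError,
    SchemaError,
    TruncatedFileError,
    UnknownElementError,
)
from .masses import is_valid_symbol

__all__ = [
    "Geometry",
    "RawQCRecord",
    "read_xyz",
    "write_xyz",
    "parse_orca_like",
    "load_mechanism",
    "save_mechanism",
    "export_results_csv",
    "RESULTS_CSV_COLUMNS",
]


@dataclass
class Geometry:
    """A molecular geometry: element symbols plus Cartesian coordinates in Å."""

    elements: list[str]
    coordinates: list[tuple[float, float, float]]
    comment: str = ""

    def __post_init__(self) -> None:
        if len(self.elements) != len(self.coordinates):
            raise ParseError(
                f"{len(self.elements)} elements vs "
                f"{len(self.coordinates)} coordinate triples"
            )
        for el in self.elements:
            if not is_valid_symbol(el):
                raise UnknownElementError(f"unknown element symbol {el!r}")
        for xyz in self.coordinates:
            if not all(math.isfinite(v) for v in xyz):
                raise ParseError(f"non-finite coordinate {xyz!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class RawQCRecord:
    """One quantum-chemistry result as read from an output file.

    ``frequencies`` are harmonic wavenumbers in cm⁻¹; imaginary modes are
    encoded as negative values.  An empty list means a single-point
    calculation.
    """

    electronic_energy: float          # Hartree
    geometry: Geometry | None = None
    frequencies: list[float] = field(default_factory=list)
    multiplicity: int = 1
    source_path: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.electronic_energy):
            raise ParseError("electronic energy is not finite")
        if self.multiplicity < 1:
            raise ParseError(f"multiplicity {self.multiplicity} < 1")


# ---------------------------------------------------------------------------
# XYZ

def read_xyz(path: str | Path) -> Geometry:
    """Read a standard XYZ file."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(
            f"{path}: first line {lines[0]!r} is not an atom count"
        ) from None
    if n < 0:
        raise ParseError(f"{path}: negative atom count {n}")
    comment = lines[1] if len(lines) > 1 else ""
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise TruncatedFileError(
            f"{path}: declared {n} atoms, found {len(body)} coordinate lines"
        )
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"{path}: malformed coordinate line {ln!r}")
        el = parts[0]
        if not is_valid_symbol(el):
            raise UnknownElementError(f"{path}: unknown element symbol {el!r}")
        try:
            x, y, z = (float(p) for p in parts[1:4])
        except ValueError:
            raise ParseError(f"{path}: malformed coordinate line {ln!r}") from None
        elements.append(el)
        coords.append((x, y, z))
    return Geometry(elements, coords, comment)


def write_xyz(geometry: Geometry, path: str | Path) -> None:
    """Write a standard XYZ file with 10 decimal places (round-trip exact)."""
    out = [str(geometry.n_atoms), geometry.comment]
    for el, (x, y, z) in zip(geometry.elements, geometry.coordinates):
        out.append(f"{el:<3s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# ORCA-like output

_ENERGY_RE = re.compile(r"FINAL SINGLE POINT ENERGY\s+(-?\d+\.\d+)")
_FREQ_HEADER_RE = re.compile(r"^\s*VIBRATIONAL FREQUENCIES\s*$")
_FREQ_LINE_RE = re.compile(r"^\s*(\d+):\s+(-?\d+\.\d+)\s+cm\*\*-1\s*$")
_COORD_HEADER_RE = re.compile(r"^\s*CARTESIAN COORDINATES \(ANGSTROEM\)\s*$")
_MULT_RE = re.compile(r"^\s*Multiplicity\s+Mult\s+\.+\s+(\d+)\s*$")


def parse_orca_like(text: str, source_path: str = "") -> RawQCRecord:
    """Parse the pinned ORCA-like output dialect (see module docstring)."""
    energies = _ENERGY_RE.findall(text)
    if not energies:
        raise MissingEnergyError(
            f"{source_path or '<text>'}: no 'FINAL SINGLE POINT ENERGY' line"
        )
    energy = float(energies[-1])  # last occurrence wins (optimization trace)

    lines = text.splitlines()
    frequencies = _parse_freq_block(lines, source_path)
    geometry = _parse_coord_block(lines, source_path)

    multiplicity = 1
    for ln in lines:
        m = _MULT_RE.match(ln)
        if m:
            multiplicity = int(m.group(1))
    return RawQCRecord(
        electronic_energy=energy,
        geometry=geometry,
        frequencies=frequencies,
        multiplicity=multiplicity,
        source_path=source_path,
    )


def _parse_freq_block(lines: Sequence[str], source: str) -> list[float]:
    try:
        start = next(
            i for i, ln in enumerate(lines) if _FREQ_HEADER_RE.match(ln)
        )
    except StopIteration:
        return []
    freqs: list[float] = []
    seen_any = False
    for ln in lines[start + 1 :]:
        if not ln.strip() or set(ln.strip()) == {"-"}:
            if seen_any:
                break
            continue  # separator rule under the header
        m = _FREQ_LINE_RE.match(ln)
        if m is None:
            if seen_any:
                break  # end of block
            raise ParseError(f"{source or '<text>'}: malformed frequency line {ln!r}")
        seen_any = True
        value = float(m.group(2))
        if value != 0.0:  # exact-zero trans/rot placeholders are dropped
            freqs.append(value)
    if not seen_any:
        raise ParseError(f"{source or '<text>'}: empty VIBRATIONAL FREQUENCIES block")
    return freqs


def _parse_coord_block(lines: Sequence[str], source: str) -> Geometry | None:
    try:
        start = next(
            i for i, ln in enumerate(lines) if _COORD_HEADER_RE.match(ln)
        )
    except StopIteration:
        return None
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for ln in lines[start + 1 :]:
        stripped = ln.strip()
        if not stripped:
            if elements:
                break
            continue
        if set(stripped) == {"-"}:
            continue
        parts = stripped.split()
        if len(parts) != 4:
            if elements:
                break
            raise ParseError(f"{source or '<text>'}: malformed coordinate line {ln!r}")
        try:
            xyz = tuple(float(p) for p in parts[1:])
        except ValueError:
            if elements:
                break
            raise ParseError(
                f"{source or '<text>'}: malformed coordinate line {ln!r}"
            ) from None
        if not is_valid_symbol(parts[0]):
            raise UnknownElementError(
                f"{source or '<text>'}: unknown element symbol {parts[0]!r}"
            )
        elements.append(parts[0])
        coords.append(xyz)  # type: ignore[arg-type]
    if not elements:
        return None
    return Geometry(elements, coords)


# ---------------------------------------------------------------------------
# Mechanism JSON (schema version 1)

_ROLES = {"minimum", "transition_state", "reference"}


def load_mechanism(path: str | Path):
    """Load a mechanism JSON document into a :class:`~microkin.network.Mechanism`.

    Schema (version 1)::

        {"version": 1,
         "networks": [{"name": str,
                       "entries": [{"name": str,
                                    "role": "minimum"|"transition_state"|"reference",
                                    "energy_hartree": num|null,
                                    "frequencies_cm1": [num]|null,
                                    "geometry_xyz": str|null,
                                    "multiplicity": int,
                                    "symmetry_number": int,
                                    "linear": bool,
                                    "source": str|null,
                                    "references": [{"name": str, "coeff": num}]}]}],
         "settings": {"temperature_K": num, "pressure_Pa": num}}
    """
    from .network import Mechanism, SpeciesRecord  # lazy: avoid import cycle

    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from None
    if not isinstance(doc, dict) or "networks" not in doc:
        raise SchemaError(f"{path}: missing 'networks' key")
    if doc.get("version") != 1:
        raise SchemaError(f"{path}: unsupported schema version {doc.get('version')!r}")

    networks: dict[str, list[SpeciesRecord]] = {}
    references: dict[str, list[tuple[str, float]]] = {}
    for net in doc["networks"]:
        name = net.get("name")
        if not isinstance(name, str) or not name:
            raise SchemaError(f"{path}: network without a name")
        records: list[SpeciesRecord] = []
        declared: set[str] = set()
        for entry in net.get("entries", []):
            rec = _entry_to_record(entry, path)
            records.append(rec)
            declared.add(rec.name)
        for entry in net.get("entries", []):
            for ref in entry.get("references", []):
                if ref["name"] not in declared:
                    raise MechanismReferenceError(
                        f"{path}: entry {entry['name']!r} references "
                        f"undeclared species {ref['name']!r}"
                    )
            if entry.get("references"):
                references[entry["name"]] = [
                    (r["name"], float(r["coeff"])) for r in entry["references"]
                ]
        networks[name] = records

    settings = doc.get("settings", {})
    return Mechanism(
        networks=networks,
        references=references,
        temperature=float(settings.get("temperature_K", 298.15)),
        pressure=float(settings.get("pressure_Pa", 101325.0)),
    )


def _entry_to_record(entry: dict, path):
    from .network import SpeciesRecord  # lazy

    role = entry.get("role")
    if role not in _ROLES:
        raise SchemaError(f"{path}: unknown role {role!r} for entry {entry.get('name')!r}")
    name = entry.get("name")
    if not isinstance(name, str) or not name:
        raise SchemaError(f"{path}: entry without a name")
    geometry = None
    if entry.get("geometry_xyz"):
        geometry = _geometry_from_xyz_string(entry["geometry_xyz"], path)
    energy = entry.get("energy_hartree")
    return SpeciesRecord(
        name=name,
        role=role,
        electronic_energy=float(energy) if energy is not None else None,
        geometry=geometry,
        frequencies=list(entry.get("frequencies_cm1") or []),
        multiplicity=int(entry.get("multiplicity", 1)),
        symmetry_number=int(entry.get("symmetry_number", 1)),
        linear=entry.get("linear"),
        source=entry.get("source"),
    )


def _geometry_from_xyz_string(text: str, path) -> Geometry:
    lines = text.splitlines()
    try:
        n = int(lines[0].strip())
    except (IndexError, ValueError):
        raise SchemaError(f"{path}: embedded XYZ has no atom-count line") from None
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise TruncatedFileError(f"{path}: embedded XYZ truncated")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        elements.append(parts[0])
        coords.append(tuple(float(p) for p in parts[1:4]))
    return Geometry(elements, coords, lines[1] if len(lines) > 1 else "")


def save_mechanism(mechanism, path: str | Path) -> None:
    """Write a mechanism back to JSON; ``load_mechanism`` inverts it."""
    doc = {
        "version": 1,
        "networks": [],
        "settings": {
            "temperature_K": mechanism.temperature,
            "pressure_Pa": mechanism.pressure,
        },
    }
    for net_name, records in mechanism.networks.items():
        entries = []
        for rec in records:
            geometry_xyz = None
            if rec.geometry is not None:
                g = rec.geometry
                rows = [str(g.n_atoms), g.comment]
                rows += [
                    f"{el} {x:.10f} {y:.10f} {z:.10f}"
                    for el, (x, y, z) in zip(g.elements, g.coordinates)
                ]
                geometry_xyz = "\n".join(rows)
            entries.append(
                {
                    "name": rec.name,
                    "role": rec.role,
                    "energy_hartree": rec.electronic_energy,
                    "frequencies_cm1": rec.frequencies or None,
                    "geometry_xyz": geometry_xyz,
                    "multiplicity": rec.multiplicity,
                    "symmetry_number": rec.symmetry_number,
                    "linear": rec.linear,
                    "source": rec.source,
                    "references": [
                        {"name": n, "coeff": c}
                        for n, c in mechanism.references.get(rec.name, [])
                    ],
                }
            )
        doc["networks"].append({"name": net_name, "entries": entries})
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV result tables

RESULTS_CSV_COLUMNS = [
    "species",
    "network",
    "temperature_K",
    "electronic_energy_hartree",
    "zpe_kcal",
    "enthalpy_kcal",
    "entropy_cal",
    "gibbs_kcal",
    "relative_energy_kcal",
]


def export_results_csv(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV (UTF-8, '.' decimal, ',' separator).

    ``results`` must carry a subset of :data:`RESULTS_CSV_COLUMNS`; missing
    columns are emitted empty so the header is fixed and documented.  An empty
    frame produces a header-only file.
    """
    frame = results.copy()
    for col in RESULTS_CSV_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    frame = frame[RESULTS_CSV_COLUMNS]
    frame.to_csv(path, index=False, encoding="utf-8", float_format="%.10g")
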