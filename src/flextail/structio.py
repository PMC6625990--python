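"""Readers/writers for the file formats the pipeline touches, and the core
coordinate containers.

The PDB support is deliberately a strict fixed-column v3.3 subset
(ATOM/HETATM/TER/MODEL/ENDMDL): coordinates in Å, author residue numbering,
altloc 'A'-or-blank kept, insertion codes rejected.  SAXS curves are 3-column
whitespace text (q, I, sigma); crosslink lists and time series are CSV.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "CrosslinkRecord",
    "SAXSCurve",
    "TraceTable",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_saxs_dat",
    "read_crosslinks_csv",
    "read_trace_csv",
]


class PDBParseError(ValueError):
    """Raised for malformed fixed-column PDB records."""


@dataclass(frozen=True)
class Atom:
    """One atom site; coordinates in Å, author (1-based) residue numbering."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_num: int
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def address(self) -> tuple[str, int]:
        return (self.chain_id, self.res_num)


class Structure:
    """Ordered collection of atoms; the universal coordinate container.

    Residue numbering within a chain is NOT assumed monotone (deposited
    structures have unmodelled loop gaps); addressing is always by
    (chain_id, res_num) in author numbering.
    """

    def __init__(self, atoms: Iterable[Atom], title: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.title = title
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.res_num, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in structure")
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise ValueError(f"non-finite coordinates for atom {key}")
            self._index[key] = i

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.atoms == other.atoms

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def get_atom(self, chain_id: str, res_num: int, name: str = "CA") -> Atom:
        try:
            return self.atoms[self._index[(chain_id, res_num, name)]]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} at residue {chain_id}/{res_num}"
            ) from None

    def has_atom(self, chain_id: str, res_num: int, name: str = "CA") -> bool:
        return (chain_id, res_num, name) in self._index

    def ca_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name == "CA"]

    def ca_coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.ca_atoms()], dtype=float)

    def residue_addresses(self) -> list[tuple[str, int]]:
        """Addresses of residues, in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.address, None)
        return list(seen)

    def select(self, addresses: Iterable[tuple[str, int]]) -> "Structure":
        wanted = set(addresses)
        return Structure([a for a in self.atoms if a.address in wanted],
                         title=self.title)

    def with_coords(self, xyz: np.ndarray) -> "Structure":
        """Copy with coordinates replaced (same atom order)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, a.res_name, a.chain_id,
                 a.res_num, float(p[0]), float(p[1]), float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return Structure(atoms, title=self.title)


@dataclass(frozen=True)
class CrosslinkRecord:
    """One crosslinked residue pair; the pair is unordered."""

    chain1: str
    res1: int
    chain2: str
    res2: int
    score: float = 0.0
    is_decoy: bool = False

    @property
    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        a, b = (self.chain1, self.res1), (self.chain2, self.res2)
        return (a, b) if a <= b else (b, a)


@dataclass
class SAXSCurve:
    """Scattering curve: momentum transfer q (Å⁻¹), intensity I, uncertainty σ."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.q) == len(self.I) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal lengths")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class TraceTable:
    """Time-series container: a shared time axis plus named signal columns.

    ``concentrations`` maps a column name to the analyte concentration (M)
    where applicable (BLI traces); other columns map to None.
    """

    t: np.ndarray
    signals: dict[str, np.ndarray]
    concentrations: dict[str, float | None] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        for name, y in list(self.signals.items()):
            y = np.asarray(y, dtype=float)
            if len(y) != len(self.t):
                raise ValueError(f"column {name!r} length mismatch")
            self.signals[name] = y

    def __len__(self) -> int:
        return len(self.t)

    def column(self, name: str) -> np.ndarray:
        return self.signals[name]


# ---------------------------------------------------------------------------
# PDB

_PDB_COORD_MAX = 10000.0  # %8.3f overflows at 10^4 Å


def _parse_atom_line(line: str, lineno: int) -> Atom:
    if len(line.rstrip("\n")) < 54:
        raise PDBParseError(
            f"line {lineno}: ATOM record shorter than 54 columns"
        )
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21]
        res_num = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed columns ({exc})") from None
    icode = line[26]
    if icode not in (" ", ""):
        raise PDBParseError(
            f"line {lineno}: insertion code {icode!r} not supported"
        )
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # standard PDB convention: element right-justified in the name field
        element = "".join(c for c in name if c.isalpha())[:1]
    return Atom(serial, name, element, res_name, chain_id, res_num, x, y, z)


def read_pdb(source: str | Path, keep_hetatm: bool = False) -> Structure:
    """Parse a fixed-column PDB file (or literal text) into a Structure.

    Only ATOM records are kept by default (``keep_hetatm=True`` adds
    HETATM — waters, ligands such as maltose or GDP).  Altloc 'A' or blank is
    kept, other altlocs dropped; insertion codes are rejected; only the first
    MODEL of a multi-model file is read (with a warning).
    """
    text = _slurp(source)
    atoms: list[Atom] = []
    title = ""
    in_first_model = True
    model_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("TITLE"):
            title = (title + " " + line[10:].strip()).strip()
        elif rec == "MODEL ":
            if model_seen:
                warnings.warn(
                    "multi-model file: only the first MODEL is read",
                    stacklevel=2,
                )
                in_first_model = False
            model_seen = True
        elif rec == "ENDMDL":
            in_first_model = False
        elif rec in ("ATOM  ", "HETATM") and in_first_model:
            if rec == "HETATM" and not keep_hetatm:
                continue
            altloc = line[16] if len(line) > 16 else " "
            if altloc not in (" ", "A"):
                continue
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PDBParseError("no ATOM records found (empty structure)")
    return Structure(atoms, title=title)


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure as fixed-column PDB text (3-decimal coordinates)."""
    if len(structure) == 0:
        raise ValueError("cannot write an empty structure")
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    prev_chain: str | None = None
    last_atom: Atom | None = None
    for a in structure.atoms:
        if max(abs(a.x), abs(a.y), abs(a.z)) >= _PDB_COORD_MAX:
            raise ValueError(
                f"coordinate magnitude >= {_PDB_COORD_MAX:g} Å overflows "
                f"the PDB format (atom {a.address}/{a.name})"
            )
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append(_ter_line(last_atom))
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name}{'':1s}{a.res_name:>3s} "
            f"{a.chain_id}{a.res_num:4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
        prev_chain = a.chain_id
        last_atom = a
    lines.append(_ter_line(last_atom))
    lines.append("END")
    return "\n".join(lines) + "\n"


def _ter_line(a: Atom | None) -> str:
    if a is None:
        return "TER"
    return f"TER   {a.serial + 1:5d}      {a.res_name:>3s} {a.chain_id}{a.res_num:4d}"


def _slurp(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if "\n" not in source and Path(source).exists():
        return Path(source).read_text()
    return source


# ---------------------------------------------------------------------------
# SAXS .dat


def read_saxs_dat(source: str | Path) -> SAXSCurve:
    """Read a 3-column (q, I, sigma) whitespace text file.

    '#'-prefixed lines are comments; columns beyond the third are ignored
    (beamline dialect drift); rows with sigma <= 0 are dropped with a warning;
    q is sorted ascending if needed (with a warning).
    """
    text = _slurp(source)
    rows: list[tuple[float, float, float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.split()
        if len(parts) < 3:
            raise ValueError(
                f"line {lineno}: expected 3 columns (q, I, sigma); the sigma "
                f"column is missing"
            )
        try:
            q, i, sig = (float(parts[0]), float(parts[1]), float(parts[2]))
        except ValueError:
            # tolerate non-numeric header rows only at the top of the file
            if not rows:
                continue
            raise ValueError(f"line {lineno}: non-numeric row") from None
        rows.append((q, i, sig))
    kept = [(q, i, s) for q, i, s in rows if s > 0]
    if len(kept) < len(rows):
        warnings.warn(
            f"dropped {len(rows) - len(kept)} rows with sigma <= 0",
            stacklevel=2,
        )
    if len(kept) < 2:
        raise ValueError("fewer than 2 usable rows in SAXS file")
    arr = np.array(kept, dtype=float)
    if np.any(np.diff(arr[:, 0]) <= 0):
        warnings.warn("q not strictly increasing; sorting", stacklevel=2)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
    return SAXSCurve(arr[:, 0], arr[:, 1], arr[:, 2])


# ---------------------------------------------------------------------------
# Crosslink CSV


def read_crosslinks_csv(source: str | Path) -> list[CrosslinkRecord]:
    """Read a crosslink table with columns chain1,res1,chain2,res2[,score][,is_decoy].

    Duplicate unordered pairs are collapsed keeping the maximum score.
    """
    if isinstance(source, str) and "\n" in source:
        buf: io.StringIO | str | Path = io.StringIO(source)
    else:
        buf = source
    df = pd.read_csv(buf)
    required = ["chain1", "res1", "chain2", "res2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df.empty:
        warnings.warn("crosslink file contains no rows", stacklevel=2)
        return []
    records: dict[tuple, CrosslinkRecord] = {}
    for idx, row in df.iterrows():
        try:
            r1, r2 = int(row["res1"]), int(row["res2"])
        except (ValueError, TypeError):
            raise ValueError(
                f"row {idx + 2}: residue fields must be integers"
            ) from None
        score = float(row["score"]) if "score" in df.columns and pd.notna(row.get("score")) else 0.0
        decoy = bool(row["is_decoy"]) if "is_decoy" in df.columns and pd.notna(row.get("is_decoy")) else False
        rec = CrosslinkRecord(str(row["chain1"]), r1, str(row["chain2"]), r2,
                              score=score, is_decoy=decoy)
        key = rec.pair_key
        if key not in records or rec.score > records[key].score:
            records[key] = rec
    return list(records.values())


# ---------------------------------------------------------------------------
# Time-series CSV


def read_trace_csv(source: str | Path, time_column: str = "t") -> TraceTable:
    """Read a time-series CSV: a time column plus one column per signal."""
    if isinstance(source, str) and "\n" in source:
        df = pd.read_csv(io.StringIO(source))
    else:
        df = pd.read_csv(source)
    if time_column not in df.columns:
        raise ValueError(f"missing time column {time_column!r}")
    t = df[time_column].to_numpy(dtype=float)
    signals = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != time_column
    }
    if len(df) < 10:
        warnings.warn("fewer than 10 time points; fits require >= 10",
                      stacklevel=2)
    return TraceTable(t=t, signals=signals)
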