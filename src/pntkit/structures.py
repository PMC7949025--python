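"""Residue-resolved structure model and PDB I/O.

The ETV6 PNT (pointed) domain construct studied here spans residues 40-125
in author numbering, and that numbering is the join key for every table in
the package: nothing is ever re-indexed from zero.  The model is deliberately
small — chains of residues carrying plain atom records — because downstream
stages only need coordinates, names, and author numbers.

Only the fixed-column ATOM/HETATM/MODEL/ENDMDL/TER subset of the PDB format
is supported.  Insertion codes are rejected (absent from the target
structures) and only the first alternate location of an atom is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "HelixAnnotation",
    "InterfaceAnnotation",
    "PdbParseError",
    "read_structure",
    "read_models",
    "write_structure",
    "select_atoms",
    "write_residue_map",
    "BACKBONE_ATOMS",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AA1_TO_3["X"] = "UNK"

#: canonical backbone atom order used for deterministic selections
BACKBONE_ATOMS = ("N", "CA", "C", "O")


class PdbParseError(ValueError):
    """Raised for malformed or unsupported PDB records."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass
class Residue:
    number: int          # author numbering (construct: 40-125)
    code: str            # one-letter amino acid code, or X
    chain_id: str = "A"
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """Ordered chains of residues with atom records."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chain(self, chain_id: str) -> list[Residue]:
        return self.chains[chain_id]

    def coordinates(self) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        return np.array([a.xyz for r in self.residues for a in r.atoms], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3), got {coords.shape}")
        i = 0
        for res in self.residues:
            for atom in res.atoms:
                atom.xyz = coords[i].copy()
                i += 1


@dataclass
class HelixAnnotation:
    """Labelled helical segments, inclusive residue ranges in author numbering."""

    segments: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        spans = sorted((s, e) for _, s, e in self.segments)
        for (s, e) in spans:
            if e < s:
                raise ValueError(f"segment end {e} before start {s}")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("helix segments overlap")

    def residues(self) -> set[int]:
        return {i for _, s, e in self.segments for i in range(s, e + 1)}

    def contains(self, resnum: int) -> bool:
        return any(s <= resnum <= e for _, s, e in self.segments)


@dataclass
class InterfaceAnnotation:
    """One self-association surface (ML = mid-loop, EH = end-helix)."""

    surface: str                # "ML" or "EH"
    residues: frozenset[int]

    def __post_init__(self) -> None:
        if self.surface not in ("ML", "EH"):
            raise ValueError(f"surface must be 'ML' or 'EH', got {self.surface!r}")
        self.residues = frozenset(self.residues)


# ---------------------------------------------------------------------------
# PDB parsing


def _parse_atom_line(line: str, lineno: int) -> tuple[str, int, str, Atom]:
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain_id = line[21]
        resnum = int(line[22:26])
        icode = line[26]
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if icode.strip():
        raise PdbParseError(f"insertion code {icode!r} at line {lineno} is not supported")
    if not element:
        element = name[:1]
    code = AA3_TO_1.get(resname, "X")
    atom = Atom(name=name, element=element, xyz=np.array([x, y, z]), occupancy=occ, b_factor=bfac)
    return chain_id, resnum, code, atom if altloc in (" ", "A") else None, altloc  # type: ignore[return-value]


def _read_single_model(lines: list[tuple[int, str]]) -> Structure:
    s = Structure()
    seen_altloc: set[tuple[str, int, str]] = set()
    for lineno, line in lines:
        chain_id, resnum, code, atom, altloc = _parse_atom_line(line, lineno)
        if atom is None:  # secondary altloc — keep the first only
            continue
        if altloc != " ":
            key = (chain_id, resnum, atom.name)
            if key in seen_altloc:
                continue
            seen_altloc.add(key)
        chain = s.chains.setdefault(chain_id, [])
        if chain and chain[-1].number == resnum and chain[-1].chain_id == chain_id:
            chain[-1].atoms.append(atom)
        else:
            if chain and resnum < chain[-1].number:
                raise PdbParseError(
                    f"residue numbers not increasing in chain {chain_id!r} at line {lineno}"
                )
            chain.append(Residue(number=resnum, code=code, chain_id=chain_id, atoms=[atom]))
    return s


def _split_models(text: str) -> list[list[tuple[int, str]]]:
    models: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            if current:
                models.append(current)
            current = []
            in_model = True
        elif rec == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append((lineno, line))
    if current or (not models and not in_model):
        if current:
            models.append(current)
    return models


def read_structure(pdb_text: str) -> Structure:
    """Parse PDB text into a :class:`Structure` (first model of multi-model files)."""
    models = _split_models(pdb_text)
    if not models or not models[0]:
        raise PdbParseError("no ATOM records found: empty structure")
    return _read_single_model(models[0])


def read_models(pdb_text: str) -> list[Structure]:
    """Parse every MODEL of a multi-model PDB file (trajectory frames)."""
    models = [m for m in _split_models(pdb_text) if m]
    if not models:
        raise PdbParseError("no ATOM records found: empty structure")
    return [_read_single_model(m) for m in models]


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    resname = AA1_TO_3.get(res.code, "UNK")
    x, y, z = atom.xyz
    return (
        f"ATOM  {serial:5d} {name:<4.4s} {resname:<3s} {res.chain_id}{res.number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_structure(s: Structure, *, model_number: int | None = None) -> str:
    """Serialize a structure as PDB ATOM records (optionally wrapped in MODEL/ENDMDL)."""
    lines: list[str] = []
    if model_number is not None:
        lines.append(f"MODEL     {model_number:4d}")
    serial = 1
    for chain_id, chain in s.chains.items():
        for res in chain:
            for atom in res.atoms:
                if abs(atom.b_factor) >= 1000:
                    raise ValueError(
                        f"B-factor value {atom.b_factor} not representable in PDB column width"
                    )
                lines.append(_format_atom_line(serial, atom, res))
                serial += 1
        lines.append(f"TER   {serial:5d}      {AA1_TO_3.get(chain[-1].code, 'UNK'):<3s} "
                     f"{chain_id}{chain[-1].number:4d}")
        serial += 1
    if model_number is not None:
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Selections and value maps


def select_atoms(
    s: Structure,
    residue_range: tuple[int, int],
    atom_class: str = "backbone",
    chain_id: str | None = None,
) -> np.ndarray:
    """Coordinates of the selected atoms, deterministic (residue, canonical atom) order.

    atom_class 'backbone' keeps N, CA, C, O; 'all' keeps every atom.
    """
    lo, hi = residue_range
    if atom_class not in ("backbone", "all"):
        raise ValueError(f"atom_class must be 'backbone' or 'all', got {atom_class!r}")
    coords: list[np.ndarray] = []
    for res in s.residues:
        if chain_id is not None and res.chain_id != chain_id:
            continue
        if not (lo <= res.number <= hi):
            continue
        if atom_class == "backbone":
            for name in BACKBONE_ATOMS:
                if res.has_atom(name):
                    coords.append(res.atom(name).xyz)
        else:
            coords.extend(a.xyz for a in res.atoms)
    if not coords:
        raise ValueError(f"empty selection: residues {lo}-{hi}, atom_class={atom_class!r}")
    return np.array(coords, dtype=float)


def write_residue_map(s: Structure, values: dict[int, float], sentinel: float = 0.0) -> str:
    """PDB text with per-residue values written into the B-factor column.

    Every atom of a residue carries the residue's value to 2 decimals; residues
    absent from ``values`` carry the sentinel.  Intended for surface coloring in
    external molecular viewers.
    """
    for v in values.values():
        if not (-999.99 <= v <= 999.99):
            raise ValueError(f"value {v} not representable in the PDB B-factor column")
    out = Structure()
    for chain_id, chain in s.chains.items():
        new_chain = []
        for res in chain:
            val = round(values.get(res.number, sentinel), 2)
            new_res = Residue(res.number, res.code, res.chain_id,
                              [Atom(a.name, a.element, a.xyz.copy(), a.occupancy, val)
                               for a in res.atoms])
            new_chain.append(new_res)
        out.chains[chain_id] = new_chain
    return write_structure(out)
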