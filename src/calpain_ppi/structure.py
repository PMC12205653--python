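"""PDB-format structure handling.

Reads atomic coordinates from PDB v3.x fixed-column text, assigns per-atom
van der Waals radii from an element table, and exposes chain-level views so
that the solvent-accessible surface of a subunit can be computed both in the
complex ("bound") and with its partner deleted ("free").  Coordinates are
never altered by chain selection: the free state is the bound geometry with
the partner removed (rigid-body assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "PDBParseError",
    "DEFAULT_RADII",
    "DEFAULT_RADIUS_FALLBACK",
    "parse_pdb",
    "assign_radii",
    "select_chains",
]

#: Element -> van der Waals radius in Angstrom.  Elements missing from the
#: table fall back to DEFAULT_RADIUS_FALLBACK with a one-time warning.
DEFAULT_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
}

DEFAULT_RADIUS_FALLBACK: float = 1.80

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "SOL"}


class PDBParseError(ValueError):
    """Raised when PDB text contains no usable atoms or a malformed field."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom from an ATOM record.

    ``radius`` is ``None`` until :func:`assign_radii` has run; SASA routines
    refuse to operate on atoms without a radius.
    """

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    chain_id: str
    res_seq: int
    insertion_code: str
    res_name: str
    x: float
    y: float
    z: float
    radius: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")
        if not self.chain_id:
            raise ValueError(f"atom {self.serial} has an empty chain id")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.serial} has non-positive radius")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.insertion_code)


class Structure:
    """An ordered collection of atoms with chain and residue lookups."""

    def __init__(self, atoms: Iterable[AtomRecord], source_id: str = "") -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        self.source_id = source_id
        seen: set[tuple] = set()
        for a in self.atoms:
            key = (a.chain_id, a.res_seq, a.insertion_code, a.atom_name, a.alt_loc)
            if key in seen:
                raise ValueError(f"duplicate atom {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.atoms == other.atoms

    @property
    def chain_ids(self) -> list[str]:
        """Chain ids in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    @property
    def chains(self) -> dict[str, list[AtomRecord]]:
        idx: dict[str, list[AtomRecord]] = {}
        for a in self.atoms:
            idx.setdefault(a.chain_id, []).append(a)
        return idx

    @property
    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        idx: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            idx.setdefault(a.residue_key, []).append(a)
        return idx

    def coordinates(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        """Per-atom radii; raises if any atom is missing one."""
        vals = []
        for a in self.atoms:
            if a.radius is None:
                raise ValueError(
                    f"atom {a.serial} ({a.chain_id}/{a.res_seq}/{a.atom_name}) "
                    "has no radius; run assign_radii first"
                )
            vals.append(a.radius)
        return np.array(vals, dtype=float)

    def to_pdb(self) -> str:
        """Serialize back to ATOM records (fixed columns, one model)."""
        lines = []
        for a in self.atoms:
            lines.append(
                "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
                "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                "{b:6.2f}          {elem:>2s}".format(
                    serial=a.serial,
                    name=_format_atom_name(a.atom_name, a.element),
                    alt=a.alt_loc or " ",
                    res=a.res_name[:3],
                    chain=a.chain_id[:1],
                    seq=a.res_seq,
                    icode=a.insertion_code or " ",
                    x=a.x,
                    y=a.y,
                    z=a.z,
                    occ=1.0,
                    b=0.0,
                    elem=a.element[:2],
                )
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def dump_tsv(self) -> str:
        """Debug table of atoms (serial, chain, residue, name, xyz, radius)."""
        rows = ["serial\tchain\tres_seq\tres_name\tatom_name\tx\ty\tz\tradius"]
        for a in self.atoms:
            r = "" if a.radius is None else f"{a.radius:.3f}"
            rows.append(
                f"{a.serial}\t{a.chain_id}\t{a.res_seq}\t{a.res_name}\t"
                f"{a.atom_name}\t{a.x:.3f}\t{a.y:.3f}\t{a.z:.3f}\t{r}"
            )
        return "\n".join(rows) + "\n"


def _format_atom_name(name: str, element: str) -> str:
    # single-letter elements start in column 14, two-letter in column 13
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _infer_element(atom_name: str) -> str:
    """Element from the atom-name columns when the element field is blank.

    Strips leading digits and returns the first alphabetic character; good
    enough for protein heavy atoms and hydrogens in pre-v3 files.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return ""


def parse_pdb(
    text: str,
    source_id: str = "",
    *,
    include_hetatm: bool = False,
    include_waters: bool = False,
    include_hydrogens: bool = False,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is read.  HETATM records, waters and hydrogens are
    excluded by default; alternate locations other than blank or 'A' are
    always dropped.

    Raises :class:`PDBParseError` if no atom survives filtering or a
    coordinate field is malformed (the error names the offending line).
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    atoms: list[AtomRecord] = []
    first_rejected: tuple[int, str] | None = None
    in_first_model = True
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("ENDMDL"):
            in_first_model = False
            continue
        if not in_first_model:
            continue
        is_atom = rec == "ATOM  " or rec.startswith("ATOM")
        is_het = rec.startswith("HETATM")
        if not (is_atom or is_het):
            continue
        if first_rejected is None:
            first_rejected = (lineno, line.rstrip())
        if is_het and not include_hetatm:
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated ATOM record")
        alt_loc = line[16].strip()
        if alt_loc not in ("", "A"):
            continue
        res_name = line[17:20].strip()
        if res_name in _WATER_NAMES and not include_waters:
            continue
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        atom_name = line[12:16].strip()
        if not element:
            element = _infer_element(atom_name)
        if element in ("H", "D") and not include_hydrogens:
            continue
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(atoms) + 1
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed coordinate field") from exc
        chain_id = line[21].strip() or "_"
        try:
            res_seq = int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed residue number") from exc
        atoms.append(
            AtomRecord(
                serial=serial,
                atom_name=atom_name,
                element=element,
                alt_loc=alt_loc,
                chain_id=chain_id,
                res_seq=res_seq,
                insertion_code=line[26].strip(),
                res_name=res_name,
                x=x,
                y=y,
                z=z,
            )
        )
    if not atoms:
        if first_rejected is not None:
            raise PDBParseError(
                f"no atoms after filtering; first candidate record at line "
                f"{first_rejected[0]}: {first_rejected[1]!r}"
            )
        raise PDBParseError("no parseable ATOM record in input")
    return Structure(atoms, source_id=source_id)


def assign_radii(
    s: Structure,
    radius_set: Mapping[str, float] = DEFAULT_RADII,
    default: float = DEFAULT_RADIUS_FALLBACK,
) -> Structure:
    """Return a copy of ``s`` with per-atom radii from an element table.

    Unknown elements receive ``default`` and trigger one warning per element;
    this is deliberately non-fatal so that odd ions in a deposited structure
    do not abort an interface calculation.
    """
    warned: set[str] = set()
    out = []
    for a in s.atoms:
        elem = a.element or _infer_element(a.atom_name)
        if elem in radius_set:
            r = radius_set[elem]
        else:
            r = default
            if elem not in warned:
                warned.add(elem)
                warnings.warn(
                    f"element {elem!r} not in radius table; using default "
                    f"{default} A",
                    stacklevel=2,
                )
        out.append(replace(a, element=elem, radius=r))
    return Structure(out, source_id=s.source_id)


def select_chains(s: Structure, chain_ids: Iterable[str] | Sequence[str]) -> Structure:
    """Sub-structure containing exactly the requested chains.

    Atom order and coordinates are unchanged (rigid-body free state).
    """
    wanted = set(chain_ids)
    available = set(s.chain_ids)
    missing = sorted(wanted - available)
    if missing:
        raise KeyError(
            f"unknown chain {','.join(missing)}; available: "
            f"{','.join(sorted(available))}"
        )
    return Structure(
        (a for a in s.atoms if a.chain_id in wanted), source_id=s.source_id
    )
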