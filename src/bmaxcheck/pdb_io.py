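"""Fixed-column PDB-format reading and writing.

The occupancy and B-factor fields live in columns 55-60 and 61-66 of an
ATOM record (1-based, wwPDB v3.3). Once an atom's B-factor reaches
100 Å² the two fields touch with no separating whitespace — the string
``" 1.00 99.99"`` becomes ``" 1.00100.00"`` — so a tokenizing parser
silently mangles exactly the atoms this package exists to flag. Parsing
here is therefore strictly positional: the two fields are sliced by
column, never split on whitespace.

Besides coordinates the parser collects the crystallographic metadata the
B_max analysis needs: the unit cell and Z value from CRYST1, resolution
from REMARK 2, R factors from REMARK 3, the data-collection temperature
from REMARK 200, the deposition year from HEADER, and the four
missing/zero-occupancy annotation blocks (REMARK 465/470/475/480).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .constants import NUCLEIC_RESIDUES, STANDARD_AA
from .errors import DegenerateCellError, EmptyStructureError, PDBFormatError

__all__ = [
    "AtomRecord",
    "UnitCell",
    "MissingReport",
    "StructureModel",
    "parse_pdb",
    "write_pdb",
    "cell_volume",
]


@dataclass
class AtomRecord:
    """One ATOM/HETATM record.

    ``atom_name`` is whitespace-stripped; the writer reconstructs the
    wwPDB alignment (element symbol in columns 13-14) from the element.
    """

    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    element: str
    is_hetatm: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_protein(self) -> bool:
        """True for non-hydrogen atoms of standard amino acids in ATOM records.

        These are the atoms that enter every B-factor and mass statistic;
        waters, ligands and hydrogens are carried along but never counted.
        """
        return (
            not self.is_hetatm
            and not self.is_hydrogen
            and self.res_name in STANDARD_AA
        )


@dataclass(frozen=True)
class UnitCell:
    """Crystal unit cell: edge lengths in Å, angles in degrees, plus the
    space group and the number of formula units Z from CRYST1."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"
    z_value: int = 0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise DegenerateCellError(f"non-positive cell edge in {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise DegenerateCellError(f"cell angle {ang} outside (0, 180)")

    @property
    def volume(self) -> float:
        return cell_volume(self)


def cell_volume(cell: UnitCell) -> float:
    """Unit-cell volume in Å³ from the standard triclinic closed form.

    V = abc * sqrt(1 - cos²α - cos²β - cos²γ + 2 cosα cosβ cosγ)
    """
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0.0:
        raise DegenerateCellError(f"degenerate cell angles: {cell}")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


@dataclass
class MissingReport:
    """Crystallographer-declared gaps in the model.

    The four lists mirror the wwPDB annotation records: residues absent
    from the coordinates (REMARK 465), missing heavy atoms (REMARK 470),
    zero-occupancy residues (REMARK 475) and zero-occupancy atoms
    (REMARK 480).
    """

    missing_residues: list[tuple[str, int, str]] = field(default_factory=list)
    missing_atoms: list[tuple[str, int, str, str]] = field(default_factory=list)
    zero_occ_residues: list[tuple[str, int, str]] = field(default_factory=list)
    zero_occ_atoms: list[tuple[str, int, str, str]] = field(default_factory=list)

    @property
    def any_missing(self) -> bool:
        return bool(
            self.missing_residues
            or self.missing_atoms
            or self.zero_occ_residues
            or self.zero_occ_atoms
        )


@dataclass
class StructureModel:
    """A parsed PDB entry: atoms plus the metadata the analysis needs."""

    entry_id: str
    atoms: list[AtomRecord]
    cell: UnitCell | None = None
    missing: MissingReport = field(default_factory=MissingReport)
    resolution: float | None = None
    r_factor: float | None = None
    free_r: float | None = None
    temperature: float | None = None
    deposition_year: int | None = None

    @property
    def contains_nucleic(self) -> bool:
        return any(a.res_name in NUCLEIC_RESIDUES for a in self.atoms)

    def protein_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_protein]

    def with_atoms(self, atoms: list[AtomRecord]) -> "StructureModel":
        return replace(self, atoms=list(atoms))


# --- parsing -----------------------------------------------------------

_RES_RE = re.compile(r"^[A-Z0-9]{1,3}$")


def _float_field(line: str, lo: int, hi: int, what: str, line_no: int) -> float:
    raw = line[lo:hi]
    try:
        return float(raw)
    except ValueError:
        raise PDBFormatError(f"non-numeric {what} field {raw!r}", line_no) from None


def _infer_element(atom_name: str, res_name: str, is_hetatm: bool) -> str:
    name = atom_name.lstrip("0123456789")
    if not name:
        return ""
    if name[0] in ("H", "D") and res_name in STANDARD_AA:
        return name[0]
    if is_hetatm and len(atom_name) >= 2 and atom_name[:2].isalpha():
        # two-letter element names (FE, ZN, ...) only occur in HETATM here
        return atom_name[:2]
    return name[0]


def _parse_atom(line: str, line_no: int) -> AtomRecord:
    if len(line) < 66:
        raise PDBFormatError("ATOM record shorter than 66 columns", line_no)
    occupancy = _float_field(line, 54, 60, "occupancy", line_no)
    b_factor = _float_field(line, 60, 66, "B-factor", line_no)
    if b_factor < 0:
        raise PDBFormatError(f"negative B-factor {b_factor}", line_no)
    if not 0.0 <= occupancy <= 1.0:
        raise PDBFormatError(f"occupancy {occupancy} outside [0, 1]", line_no)
    atom_name = line[12:16].strip()
    res_name = line[17:20].strip()
    is_hetatm = line.startswith("HETATM")
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(atom_name, res_name, is_hetatm)
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PDBFormatError(f"non-numeric serial {line[6:11]!r}", line_no) from None
    try:
        res_seq = int(line[22:26])
    except ValueError:
        raise PDBFormatError(f"non-numeric residue number {line[22:26]!r}", line_no) from None
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        alt_loc=line[16].strip(),
        res_name=res_name,
        chain_id=line[21],
        res_seq=res_seq,
        insertion_code=line[26].strip(),
        x=_float_field(line, 30, 38, "x", line_no),
        y=_float_field(line, 38, 46, "y", line_no),
        z=_float_field(line, 46, 54, "z", line_no),
        occupancy=occupancy,
        b_factor=b_factor,
        element=element,
        is_hetatm=is_hetatm,
    )


def _parse_cryst1(line: str, line_no: int) -> UnitCell:
    try:
        a = float(line[6:15]); b = float(line[15:24]); c = float(line[24:33])
        alpha = float(line[33:40]); beta = float(line[40:47]); gamma = float(line[47:54])
    except ValueError:
        raise PDBFormatError("malformed CRYST1 record", line_no) from None
    space_group = line[55:66].strip() if len(line) >= 56 else "P 1"
    z_raw = line[66:70].strip() if len(line) >= 67 else ""
    z_value = int(z_raw) if z_raw.isdigit() else 0
    return UnitCell(a, b, c, alpha, beta, gamma, space_group, z_value)


def _remark_residue_entry(tokens: list[str]) -> tuple[str, int, str] | None:
    """(chain, res_seq, res_name) from a REMARK 465/475 data line, else None."""
    if len(tokens) < 5:
        return None
    res, chain, seq = tokens[-3], tokens[-2], tokens[-1]
    if len(chain) != 1 or not _RES_RE.match(res):
        return None
    try:
        return chain, int(seq), res
    except ValueError:
        return None


def _remark_atom_entry(tokens: list[str]) -> list[tuple[str, int, str, str]]:
    """Entries from a REMARK 470/480 data line (one per listed atom)."""
    for i in range(2, len(tokens) - 3):
        res, chain, seq = tokens[i], tokens[i + 1], tokens[i + 2]
        if len(chain) == 1 and _RES_RE.match(res):
            try:
                num = int(seq)
            except ValueError:
                continue
            return [(chain, num, res, atom) for atom in tokens[i + 3:]]
    return []


_RESOLUTION_RE = re.compile(r"RESOLUTION\.\s+([\d.]+)\s+ANGSTROM")
_R_WORK_RE = re.compile(r"R VALUE\s+\(WORKING SET\)\s*:\s*([\d.]+)")
_R_FREE_RE = re.compile(r"FREE R VALUE\s*:\s*([\d.]+)")
_TEMP_RE = re.compile(r"TEMPERATURE\s+\(KELVIN\)\s*:\s*([\d.]+)")
_DATE_RE = re.compile(r"(\d{2})-[A-Z]{3}-(\d{2,4})")


def parse_pdb(text: str, entry_id: str = "") -> StructureModel:
    """Parse a PDB-format string into a :class:`StructureModel`.

    Raises :class:`EmptyStructureError` when no ATOM/HETATM record is
    present and :class:`PDBFormatError` (with line number) on malformed
    numeric fields, negative B-factors or out-of-range occupancies.
    """
    atoms: list[AtomRecord] = []
    cell: UnitCell | None = None
    missing = MissingReport()
    resolution = r_factor = free_r = temperature = None
    year = None

    for line_no, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            atoms.append(_parse_atom(line, line_no))
        elif rec == "CRYST1":
            cell = _parse_cryst1(line, line_no)
        elif rec == "HEADER":
            if not entry_id:
                entry_id = line[62:66].strip()
            m = _DATE_RE.search(line[50:59])
            if m:
                yy = int(m.group(2))
                year = yy if yy > 100 else (1900 + yy if yy >= 50 else 2000 + yy)
        elif rec == "REMARK":
            num = line[7:10].strip()
            rest = line[10:]
            if num == "2" and resolution is None:
                m = _RESOLUTION_RE.search(rest)
                if m:
                    resolution = float(m.group(1))
            elif num == "3":
                m = _R_WORK_RE.search(rest)
                if m:
                    r_factor = float(m.group(1))
                elif "FREE R VALUE" in rest and "TEST SET" not in rest and "ERROR" not in rest:
                    m = _R_FREE_RE.search(rest)
                    if m:
                        free_r = float(m.group(1))
            elif num == "200" and temperature is None:
                m = _TEMP_RE.search(rest)
                if m:
                    temperature = float(m.group(1))
            elif num in ("465", "475"):
                entry = _remark_residue_entry(line.split())
                if entry:
                    target = (missing.missing_residues if num == "465"
                              else missing.zero_occ_residues)
                    target.append(entry)
            elif num in ("470", "480"):
                entries = _remark_atom_entry(line.split())
                target = missing.missing_atoms if num == "470" else missing.zero_occ_atoms
                target.extend(entries)

    if not atoms:
        raise EmptyStructureError("no ATOM or HETATM records found")
    return StructureModel(
        entry_id=entry_id,
        atoms=atoms,
        cell=cell,
        missing=missing,
        resolution=resolution,
        r_factor=r_factor,
        free_r=free_r,
        temperature=temperature,
        deposition_year=year,
    )


# --- writing -----------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3}"
    return f"{name:<4}"


def _format_b(b: float) -> str:
    # %6.2f overflows six columns at B >= 1000; fall back to one decimal
    # so the fixed grid survives up to 9999.9 before refusing.
    if b < 1000.0:
        return f"{b:6.2f}"
    return f"{b:6.1f}"


def _write_atom(a: AtomRecord) -> str:
    if a.b_factor >= 10000.0 or a.b_factor < 0:
        raise PDBFormatError(f"B-factor {a.b_factor} not representable in columns 61-66")
    if not 0.0 <= a.occupancy <= 1.0:
        raise PDBFormatError(f"occupancy {a.occupancy} not representable")
    rec = "HETATM" if a.is_hetatm else "ATOM  "
    return (
        f"{rec}{a.serial:5d} {_format_atom_name(a.atom_name, a.element)}"
        f"{a.alt_loc or ' '}{a.res_name:>3} {a.chain_id}{a.res_seq:4d}"
        f"{a.insertion_code or ' '}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
        f"{a.occupancy:6.2f}{_format_b(a.b_factor)}"
        f"          {a.element:>2}"
    )


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to fixed-column PDB text.

    Occupancy occupies columns 55-60 and B-factor columns 61-66, both
    ``%6.2f``, so a B-factor of 100 Å² or more produces the merged
    ``"1.00100.00"`` appearance by construction.
    """
    lines: list[str] = []
    if model.deposition_year is not None:
        yy = model.deposition_year % 100
        lines.append(
            f"HEADER    PROTEIN{'':33}01-JAN-{yy:02d}   "
            f"{(model.entry_id or 'XXXX')[:4].upper():<4}"
        )
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.")
    if model.r_factor is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : {model.r_factor:.3f}")
    if model.free_r is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : {model.free_r:.3f}")
    if model.temperature is not None:
        lines.append(f"REMARK 200  TEMPERATURE           (KELVIN) : {model.temperature:.1f}")

    mr = model.missing
    if mr.missing_residues:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for chain, seq, res in mr.missing_residues:
            lines.append(f"REMARK 465     {res:>3} {chain} {seq:5d}")
    if mr.missing_atoms:
        lines.append("REMARK 470 MISSING ATOM")
        lines.append("REMARK 470   M RES CSSEQI  ATOMS")
        for chain, seq, res, atom in mr.missing_atoms:
            lines.append(f"REMARK 470     {res:>3} {chain} {seq:5d}    {atom}")
    if mr.zero_occ_residues:
        lines.append("REMARK 475 ZERO OCCUPANCY RESIDUES")
        lines.append("REMARK 475   M RES C SSSEQI")
        for chain, seq, res in mr.zero_occ_residues:
            lines.append(f"REMARK 475     {res:>3} {chain} {seq:5d}")
    if mr.zero_occ_atoms:
        lines.append("REMARK 480 ZERO OCCUPANCY ATOM")
        lines.append("REMARK 480   M RES C SSEQI  ATOMS")
        for chain, seq, res, atom in mr.zero_occ_atoms:
            lines.append(f"REMARK 480     {res:>3} {chain} {seq:5d}    {atom}")

    if model.cell is not None:
        c = model.cell
        lines.append(
            f"CRYST1{c.a:9.3f}{c.b:9.3f}{c.c:9.3f}"
            f"{c.alpha:7.2f}{c.beta:7.2f}{c.gamma:7.2f} "
            f"{c.space_group:<11}{c.z_value:4d}"
        )
    lines.extend(_write_atom(a) for a in model.atoms)
    lines.append("END")
    return "\n".join(lines) + "\n"
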