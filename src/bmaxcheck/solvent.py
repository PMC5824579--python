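"""Solvent content of a protein crystal (pcVol).

pcVol is the percentage of the unit-cell volume not occupied by protein:

    pcVol = 100 * (1 - M_cell / (rho * V_cell))

with M_cell the total protein mass in the cell (asymmetric-unit mass times
Z), rho the assumed protein density (1.34 g/cm^3 by default) and V_cell
the unit-cell volume. This is the Matthews-coefficient route to solvent
content, reformulated as a percentage.

Protein mass counts the non-hydrogen atoms of standard amino-acid
residues actually present in the coordinates (occupancy-weighted, capped
at full occupancy per site) plus the implicit hydrogens of each
polymerized residue. Ligands, ions and waters are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import gemmi

from .constants import (
    ATOMIC_MASS,
    AVOGADRO,
    PROTEIN_DENSITY,
    RESIDUE_H_COUNT,
    STANDARD_AA,
)
from .errors import BmaxError, ImplausibleContentError, UnknownCompositionError
from .pdb_io import StructureModel

__all__ = ["MassModel", "protein_mass", "pcvol", "z_from_space_group", "pcvol_of_model"]

#: Å³ of cell volume occupied per Dalton of protein at 1.34 g/cm³.
CUBIC_ANGSTROM_PER_DALTON = 1e24 / (PROTEIN_DENSITY * AVOGADRO)


@dataclass(frozen=True)
class MassModel:
    """Protein mass content of one asymmetric unit."""

    asym_mass: float  # Daltons, hydrogens included
    z_value: int
    density: float = PROTEIN_DENSITY

    def __post_init__(self):
        if self.asym_mass < 0 or self.z_value < 1 or self.density <= 0:
            raise BmaxError(f"invalid mass model: {self}")


def protein_mass(model: StructureModel) -> float:
    """Protein mass of the asymmetric unit in Daltons.

    Sums atomic masses of protein heavy atoms present in the coordinates,
    weighting alternate conformers by occupancy (capped at 1.0 per site so
    split sites are not double counted), then adds the implicit-hydrogen
    mass of every residue that contributed at least one atom.
    """
    atoms = model.protein_atoms()
    if not atoms:
        raise BmaxError("structure has no protein atoms")

    unknown = sorted(
        {(a.res_name, a.atom_name) for a in atoms if a.element not in ATOMIC_MASS}
    )
    if unknown:
        raise UnknownCompositionError(unknown)

    site_occ: dict[tuple, float] = {}
    site_elem: dict[tuple, str] = {}
    residues: set[tuple] = set()
    for a in atoms:
        site = (a.chain_id, a.res_seq, a.insertion_code, a.atom_name)
        site_occ[site] = site_occ.get(site, 0.0) + a.occupancy
        site_elem[site] = a.element
        residues.add((a.chain_id, a.res_seq, a.insertion_code, a.res_name))

    mass = sum(
        min(occ, 1.0) * ATOMIC_MASS[site_elem[site]] for site, occ in site_occ.items()
    )
    mass += sum(
        RESIDUE_H_COUNT[res_name] * ATOMIC_MASS["H"] for *_ignored, res_name in residues
    )
    return mass


def pcvol(
    asym_mass: float,
    z_value: int,
    cell_vol: float,
    density: float = PROTEIN_DENSITY,
) -> float:
    """Percent of crystal volume occupied by solvent.

    ``asym_mass`` in Daltons, ``cell_vol`` in Å³, ``density`` in g/cm³.
    Raises :class:`ImplausibleContentError` when the implied protein mass
    exceeds the cell's capacity (negative solvent fraction); warns when
    the result exceeds 95% (physically dubious, almost-empty cell).
    """
    if cell_vol <= 0 or density <= 0 or asym_mass < 0:
        raise BmaxError("cell_vol and density must be positive, asym_mass >= 0")
    mass_grams = asym_mass * z_value / AVOGADRO
    cell_cm3 = cell_vol * 1e-24
    value = 100.0 * (1.0 - mass_grams / (density * cell_cm3))
    if value < 0:
        raise ImplausibleContentError(
            f"protein mass {asym_mass * z_value:.0f} Da exceeds cell capacity "
            f"({cell_vol:.0f} Å³ at {density} g/cm³)"
        )
    if value > 95.0:
        warnings.warn(f"pcVol = {value:.1f}% — nearly empty cell", stacklevel=2)
    return value


def z_from_space_group(space_group: str) -> int:
    """Number of asymmetric units per cell from the Hermann-Mauguin symbol.

    Uses the general-position multiplicity (symmetry operations including
    centring) of the space group; covers all 65 Sohncke groups a protein
    can crystallize in.
    """
    sg = gemmi.find_spacegroup_by_name(space_group)
    if sg is None:
        raise BmaxError(f"unknown space group {space_group!r}")
    return sum(1 for _ in sg.operations())


def pcvol_of_model(model: StructureModel, density: float = PROTEIN_DENSITY) -> float:
    """pcVol of a parsed structure: mass from the coordinates, volume and Z
    from CRYST1 (falling back to the space-group multiplicity when the Z
    column is absent)."""
    if model.cell is None:
        raise BmaxError(f"{model.entry_id or 'structure'}: no CRYST1 record")
    z = model.cell.z_value
    if z <= 0:
        z = z_from_space_group(model.cell.space_group)
    return pcvol(protein_mass(model), z, model.cell.volume, density)
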