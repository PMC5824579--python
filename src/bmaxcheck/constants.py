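"""Chemical constants shared across modules.

Atomic masses are IUPAC 2021 standard atomic weights rounded to the
precision conventional in protein mass bookkeeping. Residue compositions
follow the polymerized (peptide-bond) convention: one water is lost per
residue, terminal OXT/H3 corrections are ignored (< 0.1% of chain mass).
"""

from scipy.constants import Avogadro as AVOGADRO

#: Default protein density used for solvent-content estimates, g/cm^3.
PROTEIN_DENSITY = 1.34

ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

#: The 20 standard amino acids.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue names that flag nucleic-acid content in a coordinate file.
NUCLEIC_RESIDUES = frozenset("A C G U T DA DC DG DT DU".split())

#: Canonical heavy (non-hydrogen) atom names per polymerized residue.
RESIDUE_HEAVY_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["N", "CA", "C", "O", "CB", "CG", "OD1", "ND2"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "CYS": ["N", "CA", "C", "O", "CB", "SG"],
    "GLN": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "GLY": ["N", "CA", "C", "O"],
    "HIS": ["N", "CA", "C", "O", "CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["N", "CA", "C", "O", "CB", "CG1", "CG2", "CD1"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "MET": ["N", "CA", "C", "O", "CB", "CG", "SD", "CE"],
    "PHE": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["N", "CA", "C", "O", "CB", "CG", "CD"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "THR": ["N", "CA", "C", "O", "CB", "OG1", "CG2"],
    "TRP": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "NE1", "CE2",
            "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["N", "CA", "C", "O", "CB", "CG1", "CG2"],
}

#: Hydrogen count per polymerized residue (neutral side chains, no termini).
RESIDUE_H_COUNT = {
    "ALA": 5, "ARG": 12, "ASN": 6, "ASP": 5, "CYS": 5,
    "GLN": 8, "GLU": 7, "GLY": 3, "HIS": 7, "ILE": 11,
    "LEU": 11, "LYS": 12, "MET": 9, "PHE": 9, "PRO": 7,
    "SER": 5, "THR": 7, "TRP": 10, "TYR": 9, "VAL": 9,
}


def residue_mass(res_name: str) -> float:
    """Mass in Daltons of one polymerized residue (heavy atoms + hydrogens)."""
    heavy = RESIDUE_HEAVY_ATOMS[res_name]
    mass = sum(ATOMIC_MASS[_element_of(name)] for name in heavy)
    return mass + RESIDUE_H_COUNT[res_name] * ATOMIC_MASS["H"]


def _element_of(atom_name: str) -> str:
    # Protein heavy-atom names start with their element symbol (single letter).
    return atom_name[0]


__all__ = [
    "AVOGADRO",
    "PROTEIN_DENSITY",
    "ATOMIC_MASS",
    "STANDARD_AA",
    "NUCLEIC_RESIDUES",
    "RESIDUE_HEAVY_ATOMS",
    "RESIDUE_H_COUNT",
    "residue_mass",
]
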