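"""The 24-class Li-Nussinov partition of protein heavy atoms.

Atoms are grouped by chemical environment rather than treated
individually: a backbone carbonyl carbon is essentially the same atom in
every residue, and pooling similar atoms gives each class enough members
for stable B-factor statistics. Classes 1-12 are carbon, 13-14 sulfur,
15-20 nitrogen, 21-24 oxygen; the four main-chain classes are CA (1),
carbonyl C (2), amide N (15) and carbonyl O (21).

The class table ships as ``data/atom_types.tsv`` (columns: type_id,
res_name, atom_name; res_name ``ANY`` marks the main-chain classes) and
is loaded once at import.
"""

from __future__ import annotations

from importlib import resources

from .constants import STANDARD_AA
from .errors import BmaxError, UnsupportedResidueError

__all__ = [
    "UNCLASSIFIED",
    "N_TYPES",
    "MAIN_CHAIN_TYPES",
    "classify_atom",
    "element_of_type",
    "is_main_chain",
    "types_of_element",
]

#: Sentinel for heavy atoms outside the 24-class enumeration (OXT, hydrogens,
#: legacy terminal variants).
UNCLASSIFIED = 0

N_TYPES = 24

MAIN_CHAIN_TYPES = frozenset({1, 2, 15, 21})

# legacy atom-name spellings accepted as aliases
_ALIASES = {("ILE", "CD"): ("ILE", "CD1")}


def _load_table() -> tuple[dict[str, int], dict[tuple[str, str], int]]:
    main: dict[str, int] = {}
    side: dict[tuple[str, str], int] = {}
    text = resources.files("bmaxcheck").joinpath("data/atom_types.tsv").read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        type_id_s, res, atom = line.split("\t")
        type_id = int(type_id_s)
        if res == "ANY":
            if atom in main:
                raise BmaxError(f"duplicate main-chain atom {atom} in type table")
            main[atom] = type_id
        else:
            key = (res, atom)
            if key in side:
                raise BmaxError(f"duplicate entry {key} in type table")
            side[key] = type_id
    return main, side


_MAIN_CHAIN, _SIDE_CHAIN = _load_table()

_ELEMENT_OF_TYPE = {}
for _t in range(1, N_TYPES + 1):
    _ELEMENT_OF_TYPE[_t] = "C" if _t <= 12 else "S" if _t <= 14 else "N" if _t <= 20 else "O"


def classify_atom(res_name: str, atom_name: str) -> int:
    """Map a (residue, atom) pair to its class id (1-24) or UNCLASSIFIED.

    Names are whitespace-stripped and upper-cased before lookup; the
    legacy ILE ``CD`` spelling is accepted for CD1. Raises
    :class:`UnsupportedResidueError` for non-standard residues so callers
    can skip modified residues explicitly.
    """
    res_name = res_name.strip().upper()
    atom_name = atom_name.strip().upper()
    if res_name not in STANDARD_AA:
        raise UnsupportedResidueError(f"non-standard residue {res_name!r}")
    res_name, atom_name = _ALIASES.get((res_name, atom_name), (res_name, atom_name))
    if atom_name in _MAIN_CHAIN:
        return _MAIN_CHAIN[atom_name]
    return _SIDE_CHAIN.get((res_name, atom_name), UNCLASSIFIED)


def element_of_type(type_id: int) -> str:
    """Chemical element of a class: 1-12 C, 13-14 S, 15-20 N, 21-24 O."""
    if type_id not in _ELEMENT_OF_TYPE:
        raise BmaxError(f"atom type id {type_id} outside 1..{N_TYPES}")
    return _ELEMENT_OF_TYPE[type_id]


def is_main_chain(type_id: int) -> bool:
    """True for the four backbone classes (CA, C, N, O)."""
    if not 1 <= type_id <= N_TYPES:
        raise BmaxError(f"atom type id {type_id} outside 1..{N_TYPES}")
    return type_id in MAIN_CHAIN_TYPES


def types_of_element(element: str) -> list[int]:
    """All class ids whose atoms are the given element."""
    return [t for t, e in _ELEMENT_OF_TYPE.items() if e == element]
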