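import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bmaxcheck import AtomRecord, StructureModel, SynthSpec, gen_structure, parse_pdb
from bmaxcheck.constants import RESIDUE_HEAVY_ATOMS


def make_atom(
    serial=1,
    atom_name="CA",
    res_name="ALA",
    res_seq=1,
    b=20.0,
    occ=1.0,
    alt_loc="",
    chain="A",
    element=None,
    hetatm=False,
):
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        alt_loc=alt_loc,
        res_name=res_name,
        chain_id=chain,
        res_seq=res_seq,
        insertion_code="",
        x=float(serial),
        y=0.0,
        z=0.0,
        occupancy=occ,
        b_factor=b,
        element=element or atom_name[0],
        is_hetatm=hetatm,
    )


def model_from_bs(bs, occs=None, entry_id="TST", **model_kwargs):
    """One CA atom per B value, each in its own ALA residue."""
    occs = occs if occs is not None else [1.0] * len(bs)
    atoms = [
        make_atom(serial=i + 1, res_seq=i + 1, b=b, occ=o)
        for i, (b, o) in enumerate(zip(bs, occs))
    ]
    return StructureModel(entry_id=entry_id, atoms=atoms, **model_kwargs)


def full_residue_model(residues, b=20.0, entry_id="TST", **model_kwargs):
    """Complete heavy-atom residues with a constant B-factor."""
    atoms = []
    serial = 0
    for i, res in enumerate(residues):
        for name in RESIDUE_HEAVY_ATOMS[res]:
            serial += 1
            atoms.append(
                make_atom(serial=serial, atom_name=name, res_name=res, res_seq=i + 1, b=b)
            )
    return StructureModel(entry_id=entry_id, atoms=atoms, **model_kwargs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture(scope="session")
def synthetic_entry():
    """A parsed mid-size synthetic structure with known ground truth."""
    spec = SynthSpec(
        n_residues=80,
        target_pcvol=52.0,
        b_mean=32.0,
        b_sd=7.0,
        frac_over_100=0.01,
        missing_residues=4,
        resolution=2.2,
        seed=11,
    )
    text, truth = gen_structure(spec)
    return parse_pdb(text, entry_id="SYN1"), truth, spec
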