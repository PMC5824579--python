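"""Synthetic PDB files and regression corpora with known ground truth.

The generator emulates exactly the features of a deposited entry that the
B_max analysis consumes — residue identities, occupancies, B-factors,
the unit cell (hence pcVol), resolution/temperature/R metadata and the
REMARK 465 missing-residue block. Coordinates are a chemically
meaningless extended chain: no consumer of these files reads geometry.

The unit cell is solved so that the file's solvent content equals the
requested target: a cubic cell in an orthorhombic Sohncke group (P 2₁ 2₁
2₁, Z = 4) with edge chosen by inverting the pcVol formula for the
chain's actual mass. Atomic B-factors are drawn from a normal
distribution truncated by resampling to (0, 100]; a requested fraction
of atoms is instead drawn uniformly from (100, 150] Å² to emulate
inflated, invisible atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import RESIDUE_HEAVY_ATOMS
from .errors import SynthSpecError
from .pdb_io import AtomRecord, MissingReport, StructureModel, UnitCell, parse_pdb, write_pdb
from .solvent import CUBIC_ANGSTROM_PER_DALTON, protein_mass
from .bmax_fit import FitPoint, ResolutionBins

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "gen_structure",
    "gen_regression_corpus",
    "gen_table_corpus",
]

_AA_NAMES = sorted(RESIDUE_HEAVY_ATOMS)


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic PDB entry.

    ``sequence`` is either the literal string "random" (residues drawn
    uniformly) or a sequence of 3-letter residue names. The last
    ``missing_residues`` residues of the sequence are omitted from the
    coordinates and declared in REMARK 465. Metadata defaults describe a
    well-behaved cryo-cooled entry that passes every corpus filter.
    """

    n_residues: int = 100
    sequence: str | tuple[str, ...] = "random"
    target_pcvol: float = 50.0
    b_mean: float = 30.0
    b_sd: float = 8.0
    frac_over_100: float = 0.0
    missing_residues: int = 0
    resolution: float = 2.0
    seed: int = 0
    temperature: float = 100.0
    r_factor: float = 0.20
    free_r: float = 0.25
    deposition_year: int = 2005
    entry_id: str = "SYNT"

    def __post_init__(self):
        if not 0.0 < self.target_pcvol < 95.0:
            raise SynthSpecError(f"target_pcvol {self.target_pcvol} outside (0, 95)")
        if self.b_mean <= 0 or self.b_sd < 0:
            raise SynthSpecError("b_mean must be > 0 and b_sd >= 0")
        if not 0.0 <= self.frac_over_100 <= 1.0:
            raise SynthSpecError("frac_over_100 outside [0, 1]")
        if self.missing_residues < 0 or self.missing_residues >= self.n_residues:
            raise SynthSpecError("missing_residues must be < n_residues")


@dataclass
class GroundTruth:
    """What the generator actually wrote, for round-trip checks."""

    mean_b: float           # occupancy-weighted mean of the written B values
    sd_b: float
    pcvol: float            # realized pcVol of the written (quantized) cell
    target_pcvol: float
    n_atoms: int
    n_over_100: int
    category: str
    missing_residues: list[tuple[str, int, str]] = field(default_factory=list)


def _sample_b(rng: np.random.Generator, n: int, spec: SynthSpec) -> np.ndarray:
    """B values: truncated normal on (0, 100], a chosen fraction inflated."""
    b = rng.normal(spec.b_mean, spec.b_sd, size=n)
    if spec.b_sd > 0:
        bad = (b <= 0) | (b > 100.0)
        while bad.any():
            b[bad] = rng.normal(spec.b_mean, spec.b_sd, size=int(bad.sum()))
            bad = (b <= 0) | (b > 100.0)
    n_over = int(round(spec.frac_over_100 * n))
    if n_over:
        idx = rng.choice(n, size=n_over, replace=False)
        b[idx] = rng.uniform(100.01, 150.0, size=n_over)
    return np.round(b, 2)


def gen_structure(spec: SynthSpec) -> tuple[str, GroundTruth]:
    """Generate PDB text plus its ground truth. Deterministic in the spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.sequence == "random":
        sequence = [_AA_NAMES[i] for i in rng.integers(0, len(_AA_NAMES), spec.n_residues)]
    else:
        sequence = list(spec.sequence)
        if len(sequence) != spec.n_residues:
            raise SynthSpecError("sequence length disagrees with n_residues")

    n_present = spec.n_residues - spec.missing_residues
    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(n_present):
        res = sequence[i]
        for j, name in enumerate(RESIDUE_HEAVY_ATOMS[res]):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    atom_name=name,
                    alt_loc="",
                    res_name=res,
                    chain_id="A",
                    res_seq=i + 1,
                    insertion_code="",
                    x=round(3.8 * i + 0.2 * j, 3),
                    y=round(0.5 * j, 3),
                    z=0.0,
                    occupancy=1.0,
                    b_factor=0.0,
                    element=name[0],
                    is_hetatm=False,
                )
            )
    b = _sample_b(rng, len(atoms), spec)
    for a, bi in zip(atoms, b):
        a.b_factor = float(bi)

    missing = MissingReport(
        missing_residues=[
            ("A", i + 1, sequence[i]) for i in range(n_present, spec.n_residues)
        ]
    )

    # invert the pcVol relation for a cubic cell with Z = 4
    draft = StructureModel(entry_id=spec.entry_id, atoms=atoms)
    mass = protein_mass(draft)
    z_value = 4
    occupied = mass * z_value * CUBIC_ANGSTROM_PER_DALTON
    volume = occupied / (1.0 - spec.target_pcvol / 100.0)
    edge = round(volume ** (1.0 / 3.0), 3)

    cell = UnitCell(edge, edge, edge, 90.0, 90.0, 90.0, "P 21 21 21", z_value)
    model = StructureModel(
        entry_id=spec.entry_id,
        atoms=atoms,
        cell=cell,
        missing=missing,
        resolution=spec.resolution,
        r_factor=spec.r_factor,
        free_r=spec.free_r,
        temperature=spec.temperature,
        deposition_year=spec.deposition_year,
    )
    text = write_pdb(model)

    realized_pcvol = 100.0 * (1.0 - occupied / edge**3)
    n_over = int((b > 100.0).sum())
    has_missing = missing.any_missing
    if n_over and has_missing:
        category = "large_b_and_missing"
    elif n_over:
        category = "large_b_only"
    elif has_missing:
        category = "missing_only"
    else:
        category = "clean"
    truth = GroundTruth(
        mean_b=float(b.mean()),
        sd_b=float(b.std()),
        pcvol=realized_pcvol,
        target_pcvol=spec.target_pcvol,
        n_atoms=len(atoms),
        n_over_100=n_over,
        category=category,
        missing_residues=list(missing.missing_residues),
    )
    return text, truth


def gen_regression_corpus(
    slope: float,
    intercept: float,
    noise_sd: float,
    n: int,
    pcvol_lo: float = 30.0,
    pcvol_hi: float = 70.0,
    seed: int = 0,
) -> tuple[list[FitPoint], float]:
    """(pcVol, average B) points on a known line plus Gaussian noise.

    Returns the points and the true B_max = intercept + 100·slope.
    """
    if n < 3:
        raise SynthSpecError(f"need n >= 3, got {n}")
    if not 0.0 <= pcvol_lo < pcvol_hi < 100.0:
        raise SynthSpecError("require 0 <= pcvol_lo < pcvol_hi < 100")
    rng = np.random.default_rng(seed)
    x = rng.uniform(pcvol_lo, pcvol_hi, size=n)
    y = intercept + slope * x + rng.normal(0.0, noise_sd, size=n)
    y = np.maximum(y, 0.0)
    points = [FitPoint(f"sim{i:05d}", float(xi), float(yi)) for i, (xi, yi) in enumerate(zip(x, y))]
    return points, intercept + 100.0 * slope


def gen_table_corpus(
    laws: dict[int, tuple[float, float]],
    bins: ResolutionBins = ResolutionBins(),
    n_per_bin: int = 40,
    noise_sd: float = 6.0,
    pcvol_lo: float = 30.0,
    pcvol_hi: float = 70.0,
    n_residues: int = 40,
    b_sd: float = 4.0,
    seed: int = 0,
) -> tuple[list[StructureModel], dict[int, float]]:
    """A full synthetic corpus obeying a per-bin linear B-pcVol law.

    ``laws`` maps bin index to (slope, intercept); each structure in a bin
    gets a pcVol ~ U(lo, hi), a target average B on the line plus
    N(0, noise_sd) structure-level scatter, and a resolution at the bin
    midpoint. Returns parsed models plus the true B_max per bin.
    """
    rng = np.random.default_rng(seed)
    models: list[StructureModel] = []
    truth: dict[int, float] = {}
    for bin_ix, (slope, intercept) in sorted(laws.items()):
        truth[bin_ix] = intercept + 100.0 * slope
        lo, hi = bins.edges[bin_ix - 1], bins.edges[bin_ix]
        resolution = round((lo + hi) / 2.0, 2)
        for k in range(n_per_bin):
            pv = float(rng.uniform(pcvol_lo, pcvol_hi))
            target_b = intercept + slope * pv + float(rng.normal(0.0, noise_sd))
            target_b = max(target_b, 2.0)
            spec = SynthSpec(
                n_residues=n_residues,
                target_pcvol=pv,
                b_mean=target_b,
                b_sd=min(b_sd, target_b / 3.0),
                resolution=resolution,
                seed=int(rng.integers(0, 2**31 - 1)),
                entry_id=f"B{bin_ix}S{k:03d}",
            )
            text, _ = gen_structure(spec)
            models.append(parse_pdb(text, entry_id=spec.entry_id))
    return models, truth
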