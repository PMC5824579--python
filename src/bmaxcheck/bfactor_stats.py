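"""Per-structure B-factor statistics and the underlying physics.

The B-factor encodes the mean-square displacement u² of an atom about
its equilibrium position, B = 8π²u² (Å²), and attenuates the atomic form
factor by exp(-B sin²θ/λ²). Structure-level statistics here are
occupancy-weighted over non-hydrogen protein atoms, so a split site with
occupancies 0.6/0.4 contributes one atom's worth of weight, not two.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .atom_types import UNCLASSIFIED, classify_atom
from .errors import BmaxError, DegenerateDistributionError, UnsupportedResidueError
from .pdb_io import StructureModel

__all__ = [
    "StructureBStats",
    "structure_b_stats",
    "standardized_b",
    "attenuation",
    "b_from_attenuation",
    "rms_amplitude",
    "LARGE_B_THRESHOLD",
]

#: Å² threshold above which a deposited B-factor is treated as "large":
#: the point where occupancy and B-factor merge in fixed-column PDB output.
LARGE_B_THRESHOLD = 100.0


@dataclass
class StructureBStats:
    """Occupancy-weighted B statistics of one structure's protein atoms.

    ``sd_b`` is the population (1/n-weighted) standard deviation used to
    standardize B-factors; ``per_type_mean`` maps Li-Nussinov class id to
    the weighted mean B of that class, with per-class weighted counts in
    ``per_type_count``.
    """

    entry_id: str
    mean_b: float
    sd_b: float
    n_atoms: int
    max_b: float
    n_over_100: int
    per_type_mean: dict[int, float] = field(default_factory=dict)
    per_type_count: dict[int, float] = field(default_factory=dict)


def structure_b_stats(model: StructureModel) -> StructureBStats:
    """Compute mean/spread/per-class B statistics for a parsed structure.

    Uses non-hydrogen protein atoms only; every record is weighted by its
    occupancy (records with zero occupancy carry no weight but still
    count toward ``n_over_100`` if their B exceeds 100 Å²).
    """
    atoms = model.protein_atoms()
    if not atoms:
        raise BmaxError(f"{model.entry_id or 'structure'}: no protein atoms")

    b = np.array([a.b_factor for a in atoms])
    w = np.array([a.occupancy for a in atoms])
    if w.sum() <= 0:
        raise BmaxError("all protein atoms have zero occupancy")

    mean_b = float(np.average(b, weights=w))
    sd_b = float(math.sqrt(np.average((b - mean_b) ** 2, weights=w)))

    type_ids = np.empty(len(atoms), dtype=int)
    for i, a in enumerate(atoms):
        try:
            type_ids[i] = classify_atom(a.res_name, a.atom_name)
        except UnsupportedResidueError:
            type_ids[i] = UNCLASSIFIED
    per_type_mean: dict[int, float] = {}
    per_type_count: dict[int, float] = {}
    for t in np.unique(type_ids):
        if t == UNCLASSIFIED:
            continue
        mask = type_ids == t
        if w[mask].sum() > 0:
            per_type_mean[int(t)] = float(np.average(b[mask], weights=w[mask]))
            per_type_count[int(t)] = float(w[mask].sum())

    return StructureBStats(
        entry_id=model.entry_id,
        mean_b=mean_b,
        sd_b=sd_b,
        n_atoms=len(atoms),
        max_b=float(b.max()),
        n_over_100=int((b > LARGE_B_THRESHOLD).sum()),
        per_type_mean=per_type_mean,
        per_type_count=per_type_count,
    )


def standardized_b(b: float, stats: StructureBStats) -> float:
    """Standardized B-factor BN = (B - B_av) / B_s.

    BN averages to zero over the structure by construction; per-class
    mean BN values measure how a class sits relative to its structure's
    overall B level, independent of resolution or solvent content.
    """
    if stats.sd_b <= 0:
        raise DegenerateDistributionError(
            f"{stats.entry_id or 'structure'}: zero B-factor spread"
        )
    return (b - stats.mean_b) / stats.sd_b


def attenuation(b: float, s: float) -> float:
    """Form-factor attenuation exp(-B s²) at scattering vector s = sinθ/λ (Å⁻¹)."""
    if b < 0 or s < 0:
        raise BmaxError("b and s must be non-negative")
    return math.exp(-b * s * s)


def b_from_attenuation(ratio: float, resolution: float) -> float:
    """B-factor implied by a form-factor ratio f_B/f at a given resolution.

    Inverts the attenuation with s = 1/(2·resolution):
    B = -4 ln(f_B/f) · resolution².
    """
    if not 0.0 < ratio <= 1.0:
        raise BmaxError(f"ratio {ratio} outside (0, 1]")
    if resolution <= 0:
        raise BmaxError("resolution must be positive")
    return -4.0 * math.log(ratio) * resolution * resolution


def rms_amplitude(b: float) -> float:
    """Root-mean-square oscillation amplitude u (Å) from B = 8π²u²."""
    if b < 0:
        raise BmaxError(f"negative B-factor {b}")
    return math.sqrt(b / (8.0 * math.pi**2))
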