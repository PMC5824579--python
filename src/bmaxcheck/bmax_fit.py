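"""Estimating B_max: the average B-factor extrapolated to 100% solvent.

Within a resolution bin, structure-average B-factors rise roughly
linearly with the percentage of crystal volume occupied by solvent
(pcVol). Extrapolating that line to pcVol = 100% — a crystal that is,
ab absurdo, pure liquid — gives B_max, the largest structure-average B
compatible with an ordered crystal at that resolution. The 95% band of
the extrapolated value is the standard OLS prediction-of-the-mean
interval evaluated at pcVol = 100:

    CI = 1.960 · S · sqrt(1/n + (100 - pcVol_ave)² / T)
    S  = sqrt(Σ (B_obs - B_calc)² / (n - 2))
    T  = Σ (pcVol - pcVol_ave)²

The module also ships the reference B_max table (25 atom classes × 8
resolution bins) derived from pre-2008, cryo-cooled, low-R,
redundancy-reduced PDB entries, for use when no local corpus is fitted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .atom_types import N_TYPES, MAIN_CHAIN_TYPES, types_of_element
from .bfactor_stats import structure_b_stats
from .errors import (
    BmaxError,
    DegenerateDesignError,
    InsufficientDataError,
    ResolutionOutOfRangeError,
)
from .solvent import pcvol_of_model

__all__ = [
    "DEFAULT_BIN_EDGES",
    "ResolutionBins",
    "FitPoint",
    "RegressionFit",
    "BmaxTable",
    "assign_bin",
    "fit_bmax",
    "build_table",
    "shipped_table",
]

log = logging.getLogger(__name__)

#: Default resolution bin edges in Å (8 bins, 0.0-1.5 through 3.3-4.0).
DEFAULT_BIN_EDGES = (0.0, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0, 3.3, 4.0)

#: z quantile of the 95% central interval, fixed at the conventional 1.960.
CI_Z = 1.960


@dataclass(frozen=True)
class ResolutionBins:
    """Ordered resolution bin edges; bin i covers [edges[i-1], edges[i])."""

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self):
        e = tuple(self.edges)
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise BmaxError(f"bin edges must be strictly increasing: {e}")
        object.__setattr__(self, "edges", e)

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def label(self, index: int) -> str:
        return f"{self.edges[index - 1]:.1f}-{self.edges[index]:.1f}"


def assign_bin(resolution: float, bins: ResolutionBins = ResolutionBins()) -> int:
    """1-based bin index for a resolution; bins are lower-inclusive
    half-open except the last, which is closed at its upper edge."""
    if resolution <= 0:
        raise BmaxError(f"non-positive resolution {resolution}")
    e = bins.edges
    if resolution < e[0] or resolution > e[-1]:
        raise ResolutionOutOfRangeError(
            f"resolution {resolution} Å outside [{e[0]}, {e[-1]}]"
        )
    if resolution == e[-1]:
        return bins.n_bins
    for i in range(bins.n_bins):
        if e[i] <= resolution < e[i + 1]:
            return i + 1
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class FitPoint:
    """One structure's contribution to a regression: (pcVol, average B)."""

    entry_id: str
    pcvol: float
    b_obs: float

    def __post_init__(self):
        if not 0.0 <= self.pcvol < 100.0:
            raise BmaxError(f"pcvol {self.pcvol} outside [0, 100)")
        if self.b_obs < 0:
            raise BmaxError(f"negative b_obs {self.b_obs}")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of average B on pcVol within one resolution bin."""

    slope: float       # Å² per percent
    intercept: float   # Å²
    n: int
    pcvol_ave: float   # percent
    S: float           # Å², residual scale with n-2 denominator
    T: float           # percent², Σ (pcVol - pcVol_ave)²
    b_max: float       # Å², fitted line at pcVol = 100
    ci: float          # Å², 95% interval half-width of b_max
    pearson_r: float


def fit_bmax(points: list[FitPoint]) -> RegressionFit:
    """Fit B_obs = intercept + slope·pcVol by ordinary least squares and
    extrapolate to pcVol = 100%.

    Requires at least three points with non-identical pcVol values. The
    residual scale S uses the n-2 denominator; the interval half-width is
    CI = 1.960·S·sqrt(1/n + (100 - pcVol_ave)²/T).
    """
    n = len(points)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points, got {n}")
    x = np.array([p.pcvol for p in points])
    y = np.array([p.b_obs for p in points])
    pcvol_ave = float(x.mean())
    T = float(((x - pcvol_ave) ** 2).sum())
    if T == 0.0:
        raise DegenerateDesignError("all pcVol values identical")

    res = _sps.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (intercept + slope * x)
    S = float(np.sqrt((resid**2).sum() / (n - 2)))
    b_max = intercept + 100.0 * slope
    ci = CI_Z * S * np.sqrt(1.0 / n + (100.0 - pcvol_ave) ** 2 / T)
    return RegressionFit(
        slope=slope,
        intercept=intercept,
        n=n,
        pcvol_ave=pcvol_ave,
        S=S,
        T=T,
        b_max=float(b_max),
        ci=float(ci),
        pearson_r=float(res.rvalue),
    )


# --- the per-class × per-bin table ------------------------------------

#: Key used for the all-atom row of a table.
ANY = "Any"


@dataclass
class BmaxTable:
    """(atom class ∪ "Any") × resolution bin → (B_max, CI), both in Å².

    ``cells`` maps (class_key, bin_index) where class_key is the string
    "Any" or an int 1-24 and bin_index is 1-based. Fitted tables also
    retain their full :class:`RegressionFit` objects in ``fits``.
    """

    bins: ResolutionBins
    cells: dict[tuple[str | int, int], tuple[float, float]]
    provenance: str = "fitted"
    fits: dict[tuple[str | int, int], RegressionFit] = field(default_factory=dict)

    def get(self, atom_class: str | int, bin_index: int) -> tuple[float, float] | None:
        return self.cells.get((atom_class, bin_index))

    def b_max(self, atom_class: str | int, bin_index: int) -> float:
        cell = self.get(atom_class, bin_index)
        if cell is None:
            raise BmaxError(f"no table cell for class {atom_class}, bin {bin_index}")
        return cell[0]

    def rounded(self, atom_class: str | int, bin_index: int) -> tuple[int, int]:
        """Cell rounded to integer Å², the presentation convention."""
        b, c = self.cells[(atom_class, bin_index)]
        return round(b), round(c)

    def element_mean(self, element: str, bin_index: int) -> float:
        """Mean B_max over the classes of one element in one bin."""
        vals = [
            self.cells[(t, bin_index)][0]
            for t in types_of_element(element)
            if (t, bin_index) in self.cells
        ]
        if not vals:
            raise BmaxError(f"no cells for element {element} in bin {bin_index}")
        return float(np.mean(vals))

    def chain_mean(self, main_chain: bool, bin_index: int) -> float:
        """Mean B_max over main-chain (or side-chain) classes in one bin."""
        wanted = [
            t for t in range(1, N_TYPES + 1) if (t in MAIN_CHAIN_TYPES) == main_chain
        ]
        vals = [self.cells[(t, bin_index)][0] for t in wanted if (t, bin_index) in self.cells]
        if not vals:
            raise BmaxError(f"no cells for bin {bin_index}")
        return float(np.mean(vals))

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "bin_edges": list(self.bins.edges),
            "cells": [
                {"class": k[0], "bin": k[1], "b_max": v[0], "ci": v[1]}
                for k, v in sorted(self.cells.items(), key=lambda kv: (str(kv[0][0]), kv[0][1]))
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BmaxTable":
        payload = json.loads(text)
        cells = {
            (c["class"], c["bin"]): (float(c["b_max"]), float(c["ci"]))
            for c in payload["cells"]
        }
        return cls(
            bins=ResolutionBins(tuple(payload["bin_edges"])),
            cells=cells,
            provenance=payload.get("provenance", "fitted"),
        )

    def to_tsv(self) -> str:
        """25-row × 8-column layout with integer "b_max(ci)" cells."""
        header = "atom_type\t" + "\t".join(
            self.bins.label(i) for i in range(1, self.bins.n_bins + 1)
        )
        rows = [header]
        for key in [ANY, *range(1, N_TYPES + 1)]:
            cells = []
            for i in range(1, self.bins.n_bins + 1):
                if (key, i) in self.cells:
                    b, c = self.rounded(key, i)
                    cells.append(f"{b}({c})")
                else:
                    cells.append("-")
            rows.append(f"{key}\t" + "\t".join(cells))
        return "\n".join(rows) + "\n"


#: Reference B_max table: one row per atom class ("Any" first), eight
#: integer "b_max(ci)" cells per row, bins 0.0-1.5 ... 3.3-4.0 Å.
_REFERENCE_TABLE = """\
Any 25(2) 31(2) 43(2) 55(3) 61(3) 70(5) 83(9) 80(19)
1 23(2) 30(2) 41(2) 53(3) 59(3) 68(5) 80(9) 77(19)
2 23(2) 30(2) 42(2) 54(3) 60(3) 68(5) 80(9) 77(19)
3 23(2) 30(2) 41(2) 52(3) 57(3) 64(5) 74(9) 71(19)
4 26(2) 33(2) 44(2) 56(3) 62(3) 70(5) 83(9) 84(20)
5 24(2) 31(2) 42(2) 54(3) 61(3) 70(5) 84(9) 84(20)
6 33(3) 39(2) 51(2) 64(3) 70(4) 80(5) 98(11) 102(22)
7 24(2) 31(2) 41(2) 51(3) 56(3) 63(5) 76(9) 72(19)
8 23(2) 30(2) 40(2) 51(3) 56(3) 64(5) 79(9) 72(19)
9 25(3) 32(2) 43(2) 55(3) 62(4) 70(5) 84(9) 81(21)
10 26(4) 32(3) 44(3) 56(4) 61(4) 72(6) 92(11) 90(23)
11 29(3) 35(2) 48(2) 59(3) 67(4) 79(5) 93(10) 94(21)
12 32(3) 39(3) 52(3) 65(3) 73(4) 86(6) 102(11) 106(22)
13 22(4) 25(3) 36(3) 45(4) 51(5) 64(7) 74(12) 57(25)
14 27(5) 30(4) 37(4) 44(5) 57(6) 65(8) 83(13) 76(22)
15 23(2) 30(2) 41(2) 53(3) 59(3) 68(5) 80(9) 76(19)
16 20(3) 29(3) 37(3) 43(4) 47(5) 56(7) 68(12) 63(22)
17 27(4) 32(3) 44(3) 56(4) 62(4) 72(6) 91(11) 90(24)
18 31(3) 36(2) 48(2) 59(3) 66(4) 79(5) 95(10) 94(21)
19 35(4) 38(3) 51(3) 62(3) 70(4) 80(6) 97(10) 100(24)
20 40(4) 43(3) 57(3) 69(3) 74(4) 80(5) 93(11) 98(22)
21 24(2) 30(2) 41(2) 54(3) 60(3) 69(5) 81(9) 77(19)
22 31(3) 37(2) 50(2) 61(3) 68(4) 80(5) 95(10) 95(21)
23 35(3) 41(3) 54(3) 67(3) 74(4) 87(6) 103(11) 107(22)
24 26(2) 32(2) 44(2) 56(3) 62(4) 71(5) 84(9) 85(19)
"""


def shipped_table() -> BmaxTable:
    """The reference (B_max, CI) table: 25 atom classes × 8 resolution bins."""
    bins = ResolutionBins()
    cells: dict[tuple[str | int, int], tuple[float, float]] = {}
    for row in _REFERENCE_TABLE.strip().splitlines():
        fields = row.split()
        key: str | int = fields[0] if fields[0] == ANY else int(fields[0])
        for i, cell in enumerate(fields[1:], start=1):
            b, c = cell.rstrip(")").split("(")
            cells[(key, i)] = (float(b), float(c))
    return BmaxTable(bins=bins, cells=cells, provenance="shipped-reference")


# --- fitting a table from a corpus ------------------------------------

def build_table(
    corpus,
    bins: ResolutionBins = ResolutionBins(),
    min_atoms_per_type: int = 5,
    min_points: int = 3,
) -> BmaxTable:
    """Fit a B_max table from parsed structures.

    ``corpus`` is an iterable of :class:`StructureModel` (resolution and
    CRYST1 required). For every bin, the "Any" row regresses each
    structure's overall average B on its pcVol; per-class rows use the
    class mean B of structures contributing at least
    ``min_atoms_per_type`` occupancy-weighted atoms of that class.
    Structures that fail (no cell, out-of-range resolution, ...) are
    skipped with a log message; cells with fewer than ``min_points``
    structures are left absent.
    """
    per_cell: dict[tuple[str | int, int], list[FitPoint]] = {}
    for model in corpus:
        try:
            if model.resolution is None:
                raise BmaxError("no resolution")
            bin_ix = assign_bin(model.resolution, bins)
            pv = pcvol_of_model(model)
            st = structure_b_stats(model)
        except BmaxError as exc:
            log.warning("skipping %s: %s", model.entry_id or "<unnamed>", exc)
            continue
        per_cell.setdefault((ANY, bin_ix), []).append(
            FitPoint(st.entry_id, pv, st.mean_b)
        )
        for t, mean in st.per_type_mean.items():
            if st.per_type_count[t] >= min_atoms_per_type:
                per_cell.setdefault((t, bin_ix), []).append(
                    FitPoint(st.entry_id, pv, mean)
                )

    cells: dict[tuple[str | int, int], tuple[float, float]] = {}
    fits: dict[tuple[str | int, int], RegressionFit] = {}
    for key, points in per_cell.items():
        if len(points) < max(min_points, 3):
            continue
        try:
            fit = fit_bmax(points)
        except BmaxError as exc:
            log.warning("cell %s: %s", key, exc)
            continue
        cells[key] = (fit.b_max, fit.ci)
        fits[key] = fit
    return BmaxTable(bins=bins, cells=cells, provenance="fitted", fits=fits)
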