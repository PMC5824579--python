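"""Applying B_max thresholds to single entries and corpora.

An entry passes when its structure-average B-factor does not exceed the
B_max of its resolution bin; exceeding B_max, and a fortiori B_max + CI,
marks a structure whose model is likely to contain atoms refined to
B-factors too large to correspond to anything visible in the density.
Entries are also sorted into the four deposition categories defined by
two booleans: any atom with B > 100 Å², and any crystallographer-declared
missing/zero-occupancy content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bfactor_stats import LARGE_B_THRESHOLD, structure_b_stats
from .bmax_fit import ANY, BmaxTable, ResolutionBins, assign_bin
from .errors import BmaxError, ResolutionOutOfRangeError, UntrimmableError
from .pdb_io import AtomRecord, StructureModel
from .solvent import pcvol_of_model

__all__ = [
    "EntryCategory",
    "ValidationReport",
    "FilterRules",
    "categorize_entry",
    "validate_entry",
    "trim_to_bmax",
    "filter_corpus",
    "corpus_fraction_over_bmax",
]

CATEGORY_NAMES = (
    "clean",                 # no large B, nothing missing
    "large_b_only",
    "missing_only",
    "large_b_and_missing",
)


@dataclass(frozen=True)
class EntryCategory:
    """Two-boolean deposition category of a PDB entry."""

    has_large_b: bool
    has_missing: bool

    @property
    def name(self) -> str:
        if self.has_large_b and self.has_missing:
            return "large_b_and_missing"
        if self.has_large_b:
            return "large_b_only"
        if self.has_missing:
            return "missing_only"
        return "clean"


def categorize_entry(model: StructureModel) -> EntryCategory:
    """Classify an entry by large B-factors (any protein atom strictly
    above 100 Å²) and declared missing content (REMARK 465/470/475/480)."""
    atoms = model.protein_atoms()
    has_large = any(a.b_factor > LARGE_B_THRESHOLD for a in atoms)
    return EntryCategory(has_large_b=has_large, has_missing=model.missing.any_missing)


@dataclass
class ValidationReport:
    """Per-entry verdict against a B_max table."""

    entry_id: str
    resolution: float
    bin_index: int
    pcvol: float
    mean_b: float
    b_max: float
    ci: float
    verdict: str  # pass | above_bmax | above_bmax_plus_ci
    category: EntryCategory
    trimmed_atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def validate_entry(
    model: StructureModel,
    table: BmaxTable,
    resolution: float | None = None,
    trim: bool = False,
) -> ValidationReport:
    """Compare a structure's average B-factor with the B_max of its bin.

    The verdict is graded: ``pass`` when mean B ≤ B_max, ``above_bmax``
    when it exceeds B_max but not B_max + CI, ``above_bmax_plus_ci``
    beyond that. ``resolution`` overrides the value parsed from REMARK 2
    (sidecar metadata). With ``trim=True`` the report lists the
    highest-B atoms whose removal brings the average under B_max.
    """
    res = resolution if resolution is not None else model.resolution
    if res is None:
        raise ResolutionOutOfRangeError(
            f"{model.entry_id or 'entry'}: no resolution available"
        )
    bin_ix = assign_bin(res, table.bins)
    cell = table.get(ANY, bin_ix)
    if cell is None:
        raise BmaxError(f"table has no 'Any' cell for bin {bin_ix}")
    b_max, ci = cell

    stats = structure_b_stats(model)
    pv = pcvol_of_model(model) if model.cell is not None else float("nan")
    if stats.mean_b <= b_max:
        verdict = "pass"
    elif stats.mean_b <= b_max + ci:
        verdict = "above_bmax"
    else:
        verdict = "above_bmax_plus_ci"

    trimmed: list[AtomRecord] = []
    if trim and verdict != "pass":
        _, trimmed = trim_to_bmax(model, b_max)
    return ValidationReport(
        entry_id=model.entry_id,
        resolution=res,
        bin_index=bin_ix,
        pcvol=pv,
        mean_b=stats.mean_b,
        b_max=b_max,
        ci=ci,
        verdict=verdict,
        category=categorize_entry(model),
        trimmed_atoms=trimmed,
    )


def trim_to_bmax(
    model: StructureModel, b_max: float
) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Remove highest-B protein atoms until the remaining average is ≤ B_max.

    Atoms are removed in descending B order (ties kept in input order),
    which is the minimal-cardinality removal for lowering a (weighted)
    mean. Returns (kept, removed); atoms that never enter the statistics
    (hydrogens, HETATM, waters) are always kept. Raises
    :class:`UntrimmableError` when even a single remaining atom would
    exceed the threshold.
    """
    if b_max <= 0:
        raise BmaxError(f"b_max must be positive, got {b_max}")
    protein = model.protein_atoms()
    if not protein:
        raise BmaxError("no protein atoms to trim")

    order = sorted(range(len(protein)), key=lambda i: -protein[i].b_factor)
    b = np.array([protein[i].b_factor for i in order])
    w = np.array([protein[i].occupancy for i in order])
    # weighted mean of the suffix after removing the k largest-B atoms
    sw = np.cumsum((b * w)[::-1])[::-1]
    ww = np.cumsum(w[::-1])[::-1]
    removed_set: set[int] = set()
    for k in range(len(protein)):
        if ww[k] > 0 and sw[k] / ww[k] <= b_max:
            removed_set = set(order[:k])
            break
    else:
        raise UntrimmableError(
            f"no non-empty suffix of atoms has mean B <= {b_max}"
        )
    removed = [protein[i] for i in sorted(removed_set)]
    removed_ids = {id(a) for a in removed}
    kept = [a for a in model.atoms if id(a) not in removed_ids]
    return kept, removed


@dataclass(frozen=True)
class FilterRules:
    """Corpus-selection rules for building a well-controlled fitting set.

    Defaults mirror the selection used for the reference table: reject
    entries with R or free R above 0.3, data-collection temperature
    outside 95-105 K, or nucleic-acid content; optionally keep only
    entries deposited before ``max_year``. ``r_either`` toggles between
    rejecting when either R factor exceeds the cutoff (default, stricter)
    and only when both do.
    """

    max_r: float = 0.3
    r_either: bool = True
    temp_range: tuple[float, float] = (95.0, 105.0)
    reject_nucleic: bool = True
    max_year: int | None = None  # keep entries with deposition_year < max_year
    require_metadata: bool = True


def _check_entry(model: StructureModel, rules: FilterRules) -> str | None:
    """Reason for rejection, or None if the entry is kept."""
    r, fr = model.r_factor, model.free_r
    if rules.require_metadata and (r is None or fr is None or model.temperature is None):
        return "missing metadata"
    if r is not None and fr is not None:
        exceed_r, exceed_fr = r > rules.max_r, fr > rules.max_r
        bad = (exceed_r or exceed_fr) if rules.r_either else (exceed_r and exceed_fr)
        if bad:
            return f"R/free-R above {rules.max_r}"
    if model.temperature is not None:
        lo, hi = rules.temp_range
        if not lo <= model.temperature <= hi:
            return f"temperature {model.temperature} K outside [{lo}, {hi}]"
    if rules.reject_nucleic and model.contains_nucleic:
        return "contains nucleic acids"
    if rules.max_year is not None:
        if model.deposition_year is None:
            return "missing metadata"
        if model.deposition_year >= rules.max_year:
            return f"deposited in {model.deposition_year} (cutoff {rules.max_year})"
    return None


def filter_corpus(
    entries: list[StructureModel], rules: FilterRules = FilterRules()
) -> tuple[list[StructureModel], list[tuple[StructureModel, str]]]:
    """Split a corpus into (kept, rejected-with-reason) under the rules."""
    kept: list[StructureModel] = []
    rejected: list[tuple[StructureModel, str]] = []
    for model in entries:
        reason = _check_entry(model, rules)
        if reason is None:
            kept.append(model)
        else:
            rejected.append((model, reason))
    return kept, rejected


def corpus_fraction_over_bmax(
    reports: list[ValidationReport],
    bins: ResolutionBins = ResolutionBins(),
) -> dict[int, float]:
    """Per-bin percentage of entries whose average B exceeds B_max.

    Bins with no reports are absent from the result rather than zero.
    """
    totals: dict[int, int] = {}
    over: dict[int, int] = {}
    for rep in reports:
        totals[rep.bin_index] = totals.get(rep.bin_index, 0) + 1
        if not rep.passed:
            over[rep.bin_index] = over.get(rep.bin_index, 0) + 1
    return {
        b: 100.0 * over.get(b, 0) / n for b, n in sorted(totals.items())
    }
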