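# Methods

## Model

The package treats a protein crystal as two compartments: protein
occupying a fraction 1 − pcVol/100 of the unit cell, and liquid solvent
occupying the rest. The structure-average B-factor ⟨B⟩ of entries refined
at similar resolution is modelled as linear in pcVol,

    ⟨B⟩ = α + β · pcVol + ε,      ε ~ N(0, σ²) i.i.d. across entries,

and B_max is the model's mean response at pcVol = 100 %, the solvent-only
limit where, by construction, nothing is orderable. The half-width of the
95 % interval of that extrapolated mean is

    CI = 1.960 · S · √(1/n + (100 − p̄)² / T),
    S  = √(Σ residual² / (n − 2)),    T = Σ (pcVol − p̄)².

The z constant is fixed at 1.960 rather than the t(n−2) quantile: the
interval is defined that way in the formulation this package implements,
and with the corpus sizes involved (tens to thousands of structures per
bin) the difference is below a percent of the CI. For very small local
fits this makes the interval slightly anti-conservative; `RegressionFit.n`
is exposed so callers can judge.

Assumptions worth stating explicitly: (i) the linearity is an empirical
observation over pcVol ≈ 30–80 % and the extrapolation leaves the
observed range — B_max inherits that risk; (ii) entries are treated as
exchangeable within a bin (no weighting by size or quality); (iii) pcVol
is a mass-balance estimate, not a measured quantity.

## Solvent content

pcVol = 100·(1 − M_cell/(ρ·V_cell)) with ρ = 1.34 g/cm³ (the conventional
protein density; at that density one Dalton of protein occupies
1.2392 Å³). M_cell = asymmetric-unit protein mass × Z. The mass counts
non-hydrogen atoms of standard amino-acid residues present in the
coordinates — occupancy-weighted, with each (chain, residue, atom) site
capped at total occupancy 1.0 so alternate conformers are not double
counted — plus the implicit hydrogens of each polymerized residue
(peptide-bond convention; terminal OXT/H corrections are ignored, < 0.1 %
of chain mass). Ligands, ions, glycans and waters are excluded: the
numerator is protein mass specifically. Z comes from CRYST1 columns
67–70 when present, otherwise from the general-position multiplicity of
the CRYST1 space group (via gemmi), which covers all 65 Sohncke groups.

## Atom classes

Protein heavy atoms are pooled into 24 chemically homogeneous classes
(backbone CA/C/N/O plus 20 side-chain groups; 12 carbon, 2 sulfur, 6
nitrogen, 4 oxygen classes) rather than treated per (residue, atom) pair:
a backbone carbonyl carbon is essentially identical in every residue, and
pooling gives each class the statistics the per-class regressions need.
The table ships as `data/atom_types.tsv` and is applied verbatim —
atoms outside the enumeration (OXT, terminal variants, hydrogens) are
UNCLASSIFIED and excluded from per-class statistics, not guessed. The
one legacy alias accepted is ILE `CD` → `CD1`.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| protein density ρ | 1.34 g/cm³ | mass→volume conversion in pcVol |
| resolution bin edges | 0.0, 1.5, 1.8, 2.1, 2.4, 2.7, 3.0, 3.3, 4.0 Å | 8 bins, lower-inclusive, last bin closed |
| CI constant | 1.960 | 95 % central interval |
| large-B threshold | 100 Å² (strict >) | deposition-category flag; also where PDB fields merge |
| R / free-R cutoff | 0.3, reject if **either** exceeds | corpus filter (both-exceed reading available via `FilterRules(r_either=False)`) |
| temperature window | 95–105 K | corpus filter (cryo-cooled entries only) |
| min atoms per class | 5 (occupancy-weighted) | floor for a structure to contribute a per-class fit point |
| verdict boundary | pass iff mean B ≤ B_max | "exceeds" means strictly greater |

The per-class floor of 5 atoms is this package's stabilizer (small
structures would otherwise contribute single-atom "means"); it is
configurable on `build_table`.

## Numerical and convention choices

- **Fixed-column parsing.** Occupancy (cols 55–60) and B (cols 61–66) are
  sliced by position; the merged `1.00100.00` appearance at B ≥ 100 Å²
  parses correctly by construction. Non-numeric fields, negative B, or
  occupancy outside [0, 1] raise errors carrying the line number.
- **Writer overflow.** `%6.2f` overflows six columns at B ≥ 1000 Å²; the
  writer switches to one decimal (`%6.1f`) up to 9999.9 to preserve the
  column grid, and refuses B ≥ 10000.
- **Standardized B (BN).** BN = (B − B_av)/B_s with B_s the *population*
  (1/n) standard deviation: standardization is within one complete
  structure, not an estimate from a sample, and the z-score form requires
  a standard deviation, not a variance.
- **Occupancy weighting.** All structure-level B statistics weight
  records by occupancy, so a split site with occupancies 0.6/0.4
  contributes one atom's worth of weight. With all occupancies 1 this
  reduces to the plain mean.
- **Bins.** Lower-inclusive half-open bins, last bin closed at 4.0 Å;
  resolutions outside [0, 4] Å are an explicit out-of-range signal, not
  silently clamped.
- **Trimming.** Removing atoms in descending-B order is provably the
  minimal-cardinality way to lower a weighted mean, so `trim_to_bmax` is
  greedy; ties keep input order. If even one remaining atom exceeds the
  threshold the entry is reported untrimmable rather than emptied.
- **OLS route.** Fits go through `scipy.stats.linregress`; the test suite
  checks them against normal equations evaluated in exact rational
  arithmetic, and the CI coverage against 500-replicate simulation.

## The synthetic generator

`bmaxcheck.synthetic` emulates exactly the features of a deposited entry
that this analysis reads: residue identities, occupancies, per-atom
B-factors, CRYST1 (hence pcVol), resolution/temperature/R/year metadata,
and the REMARK 465 block. The unit cell is solved by inverting the pcVol
formula for the generated chain's actual mass (cubic cell, P 2₁ 2₁ 2₁,
Z = 4), so the requested solvent content is reproduced to the CRYST1
precision (±0.2 % tolerance in tests). B-factors are drawn from
N(b_mean, b_sd) truncated to (0, 100] by resampling (keeps the mean
unbiased within ~0.1 % for b_sd ≤ b_mean/3); a requested fraction of
atoms is instead drawn from U(100.01, 150] to emulate inflated invisible
atoms. Default metadata (100 K, R 0.20/0.25, deposited 2005, 2.0 Å,
pcVol 50 %, B ~ N(30, 8)) describes a typical well-behaved cryo-era entry
that passes every corpus filter. Generation is deterministic: one named
PRNG seeded from the spec, samples drawn in documented order, and a given
spec yields byte-identical PDB text.

What the generator does **not** emulate: real stereochemistry (the chain
is an extended placeholder; no consumer reads geometry), spatially
correlated B-factors, anisotropic displacement, alternate conformers,
ligands, or the long-tailed B distributions of real depositions. Tests
passing on synthetic corpora therefore demonstrate the correctness of
the *computational pipeline* (parsing → mass → pcVol → statistics →
regression → verdicts) under the stated statistical model, not the
empirical adequacy of the linear B–pcVol law for any particular real
corpus.

## Problem sizes

The simulation-based checks use 500 replicate corpora of n = 200 points
for interval coverage, and 60 structures per bin × 8 bins (≈ 300 atoms
each) for end-to-end table recovery — sizes at which the coverage
estimate has ≲ 1 % standard error and each per-bin fit is comfortably
determined, while the whole suite runs in seconds.

## Known limitations

- B_max is an extrapolation ~20–70 pcVol-points beyond the data; only
  electron-density inspection can definitively confirm whether a given
  atom is visible, and this tool makes no attempt at that.
- The shipped reference table cannot be re-derived here (it summarizes a
  bulk, redundancy-reduced pre-2008 corpus); `bmax fit` refits the same
  quantities from any corpus you can supply.
- mmCIF input is out of scope; the fixed-column pathology this package
  guards against is PDB-format specific. Multi-model NMR files and
  modified residues are not handled beyond being ignored/flagged.
- Sequence-redundancy reduction is accepted as an external include list,
  not computed.
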