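# bmaxcheck

**How large can the B-factors of a protein crystal structure legitimately
be?** `bmaxcheck` answers that question with an explicit upper bound,
B<sub>max</sub>, and applies it as a validation criterion to PDB entries.

## The problem

Crystallographic B-factors (atomic displacement parameters) encode the
mean-square displacement of an atom about its equilibrium position,
*B* = 8π²⟨*u*²⟩ (Å²), and attenuate the atomic form factor as
*f* = *f*₀·exp(−*B* sin²θ/λ²). Because refinement programs place no upper
restraint on *B*, atoms that are invisible in the electron density are
routinely deposited with B-factors above 100 Å² — at which point their
contribution to the structure factors is negligible and their coordinates
are speculation, not measurement. (Above 100 Å² the occupancy and
B-factor fields of a PDB ATOM record also physically merge:
`1.00 99.99` becomes `1.00100.00`, which breaks every whitespace-based
parser.)

## The bound

A physically motivated ceiling comes from solvent content. For a set of
structures at similar resolution, the structure-average B-factor ⟨*B*⟩
rises roughly linearly with the percentage of crystal volume occupied by
solvent,

pcVol = 100·(1 − M<sub>cell</sub> / (ρ·V<sub>cell</sub>)),  ρ = 1.34 g/cm³,

the Matthews-coefficient route to solvent content. Extrapolating the OLS
line ⟨*B*⟩ = α + β·pcVol to pcVol = 100 % — a crystal that is, *ab
absurdo*, pure liquid — gives **B<sub>max</sub> = α + 100β**, the largest
average B compatible with an ordered crystal in that resolution bin. Its
95 % band is the standard prediction-of-the-mean interval at pcVol = 100:

CI = 1.960·S·√(1/n + (100 − p̄)²/T),  S² = Σ(B<sub>obs</sub> −
B<sub>calc</sub>)²/(n−2),  T = Σ(pcVol − p̄)².

The package ships a reference table of (B<sub>max</sub>, CI) for 8
resolution bins (0.0–1.5 … 3.3–4.0 Å) × 25 atom classes ("Any" plus the
24 Li–Nussinov types), derived from pre-2008, cryo-cooled (95–105 K),
R/R<sub>free</sub> ≤ 0.3, redundancy-reduced protein entries — the era
before B-factor inflation became common. At the highest resolution
B<sub>max</sub> ≈ 25 Å²; in the lowest bin it reaches ≈ 80 Å². It can
also refit the whole table from any corpus you supply.

## Worked example

Generate two synthetic entries — one well-behaved, one with inflated
B-factors and missing residues — and validate them against the shipped
table:

```sh
bmax simulate structure --pcvol 45 --bmean 30 --bsd 8  --n-res 120 --seed 7 -o entry1.pdb
bmax simulate structure --pcvol 60 --bmean 55 --bsd 10 --frac-over-100 0.04 \
     --missing 6 --resolution 2.0 --seed 8 -o entry2.pdb
bmax validate entry1.pdb entry2.pdb
```

```
entry_id  resolution  bin  pcvol  mean_b  b_max  ci   verdict             category
entry1    2.00        3    45.0   29.46   43.0   2.0  pass                clean
entry2    2.00        3    60.0   57.96   43.0   2.0  above_bmax_plus_ci  large_b_and_missing
```

Both entries fall in resolution bin 3 (1.8–2.1 Å), where the reference
B<sub>max</sub> is 43 ± 2 Å². `entry1`'s average B of 29.46 Å² is
comfortably below the ceiling: *pass*. `entry2` averages 57.96 Å², above
even B<sub>max</sub> + CI = 45 Å², and carries both hallmarks of an
over-interpreted deposition: 30 atoms with B > 100 Å² and a REMARK 465
block of unmodelled residues. Its ATOM records show the merged field the
fixed-column parser exists for:

```
ATOM     37  OD2 ASP A   5      16.600   3.500   0.000  1.00100.94           O
```

`bmax scan <dir>` tabulates per-entry statistics and the four deposition
categories (large-B × missing-residue), `bmax fit <dir> --out table.json`
refits a B<sub>max</sub> table from your own corpus (applying the
R-factor/temperature/nucleic-acid selection filters first), and with
`--trim` the validator lists the highest-B atoms whose removal would
bring an entry back under B<sub>max</sub>.

The same functionality is available as a library:

```python
from bmaxcheck import parse_pdb, shipped_table, validate_entry

model = parse_pdb(open("entry2.pdb").read(), entry_id="entry2")
report = validate_entry(model, shipped_table())
print(report.verdict, report.mean_b, report.b_max)   # above_bmax_plus_ci 57.96 43.0
```

## Layout

- `bmaxcheck.pdb_io` — strict fixed-column PDB reader/writer (the merged
  occupancy/B field is handled by column slicing, never by splitting).
- `bmaxcheck.solvent` — protein mass (implicit hydrogens, occupancy-capped
  sites) and pcVol; space-group → Z lookup.
- `bmaxcheck.atom_types` — the 24-class atom typing (shipped as
  `data/atom_types.tsv`).
- `bmaxcheck.bfactor_stats` — occupancy-weighted structure statistics,
  standardized B (BN), the B ↔ attenuation ↔ resolution relations.
- `bmaxcheck.bmax_fit` — per-bin OLS extrapolation, CI, the shipped and
  refittable B<sub>max</sub> tables.
- `bmaxcheck.validate` — verdicts, deposition categories, corpus filters,
  B-capped trimming.
- `bmaxcheck.synthetic` — synthetic PDB files and corpora with known
  ground truth (see `docs/methods.md` for what they do and do not emulate).
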