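# dqcryst

Distance-based NMR-crystallography validation of crystal-structure models.

Given a crystal-structure model (CIF) and a grouping of its proton sites,
the package computes all periodic ¹H–¹H contacts up to a cutoff, aggregates
them into squared effective dipolar couplings (with optional fast 3-site
methyl motional scaling), normalizes them into fractional intensities, and
compares them against experimental fractional intensities from a single
short-excitation 2Q–1Q ¹H correlation spectrum: an R² statistic, per-pair
effective-distance deviations and their rmsd. A parallel chemical-shift arm
converts calculated shieldings to shifts via a fitted reference intercept,
assigns experimental shifts to sites, and reports per-site deviations and
rmsd. A synthetic-data module generates toy structures, noisy fraction
sets, and synthetic shieldings so every stage is testable offline.

## Layout

- `dqcryst.structures` — CIF read/write, symmetry expansion to P1,
  periodic pair-distance enumeration.
- `dqcryst.dipolar` — couplings, squared effective couplings, multiplicity,
  effective distances, model fractions.
- `dqcryst.spectra` — linear 2Q–1Q spectrum simulation and rectangular
  peak integration.
- `dqcryst.validation` — R², NMR-referenced distances, deviations/rmsd,
  full `validate()` pipeline.
- `dqcryst.shifts` — isotropic averaging, shielding→shift referencing,
  constrained assignment, deviation statistics.
- `dqcryst.synthetic_data` — toy structure generators, brute-force
  supercell oracle, noise models, synthetic shieldings.
- `dqcryst.datasets` — packaged reference tables (per-site shifts and
  per-pair fractions/effective distances for the three paracetamol-based
  structures, transcribed as printed).

## CLI

```sh
dqcryst make-fixtures --out-dir fixtures       # reference tables + toy CIFs
dqcryst fractions fixtures/methyl_triangle.cif fixtures/methyl_triangle_groups.json
dqcryst validate  model.cif groups.json f_nmr.tsv --out-json report.json
dqcryst simulate  model.cif groups.json --out-tsv spectrum.tsv
dqcryst shift-compare exp_shifts.tsv calc_shieldings.tsv --species 1H
```

Group configs are JSON lists of `{"id", "members", "motion", "shift"}`;
experimental fraction TSVs carry `pair` and `f` columns (optional
`excluded`). Common flags: `--cutoff-pm` (default 1000), `--mult-tol`
(default 0.10), `--motion GROUP=fast_3site`, `--exclude PAIR`.

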