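# pkadirect

Direct-approach computational pKa toolkit for phenolic compounds.

Predicting the acidity of a phenol from first principles is a standard task
in drug-discovery and natural-product chemistry, but most published recipes
need an empirical proton solvation free energy or a fitted correction to
land near experiment. This package implements the correction-free
alternative: write the dissociation as a **charge-conserving exchange with
hydroxide**, microsolvate every species with the same number *n* of
explicit water molecules inside a continuum solvent, and convert the
reaction electronic energy directly into a pKa.

```
HA·(H2O)n + OH⁻·(H2O)n  ⇌  A⁻·(H2O)n + H2O·(H2O)n

ΔE_dep = E(A⁻) + E(H2O) − E(OH⁻) − E(HA)        [kcal·mol⁻¹]

pKa = ΔE_dep / (ln10·R·T) + 15.74                (T = 298.15 K)
```

Because the number of charged species is the same on both sides, the large
and poorly known solvation terms cancel, and the additive constant 15.74
(the aqueous pKa of water left behind by the hydroxide reference) is a
protocol constant, not a regression intercept.

The DFT engine itself is external (any code that prints SCF energies);
everything around it lives here:

| module | what it does |
| --- | --- |
| `core_thermo` | constants, reaction energy, the pKa ↔ energy affine map |
| `qc_io` | Gaussian-style log parsing, energy-table CSV, input decks, true-minimum validation |
| `microsolvation` | deterministic explicit-water starting geometries, H-bond lengths, open/closed cage classification, atom balance |
| `benchmark` | ΔpKa, MAE, error spread, extreme deviations, calc-vs-exp slope; bundled 13-phenol reference set |
| `titration` | experimental pKa by sigmoidal fit of absorbance vs pH |
| `fixtures` | synthetic energy sets, mock QC logs, template geometries |
| `cli` | `pkadirect compute / benchmark / titrate / geninput / validate` |

## Worked example

Compute a pKa from a four-species energy table (here generated
synthetically for a target of 10.27; with a real engine the CSV holds your
four final SCF energies in Hartree):

```python
from pkadirect import qc_io, compute_pka
from pkadirect.fixtures import FixtureSpec, make_energy_set

system = make_energy_set(FixtureSpec(target_pka=10.27, seed=2))
qc_io.write_energy_table(list(system.records), "energies.csv")

records = qc_io.read_energy_table("energies.csv")
result = compute_pka(qc_io.system_from_records(records))
print(f"dE_dep = {result.delta_E_dep:.4f} kcal/mol -> pKa = {result.pka:.2f}")
```

prints

```
dE_dep = -7.4624 kcal/mol -> pKa = 10.27
```

i.e. a reaction energy 7.46 kcal/mol below the water anchor moves the pKa
5.47 units below 15.74 (one pKa unit per ln10·R·T = 1.364 kcal/mol).

Benchmark statistics over the bundled 13-phenol set, for the two-water
CAM-B3LYP/SMD protocol:

```bash
$ pkadirect benchmark --bundled --method "2H2O/CAM-B3LYP/SMD" --format tsv | tail -5
MAE     0.38
Std. dev.       0.30
Max pos 0.89
Max neg -0.60
Slope (origin)  1.019
```

A mean absolute error of 0.38 pKa units with a calc-vs-exp slope of 1.019
(ideal: 1.000) — including the nitro- and cyano-substituted phenols that
correction-free methods usually miss. Fit an experimental titration curve
(absorbance vs pH CSV):

```bash
pkadirect titrate curve.csv        # -> pKa = 7.38 +/- 0.01 (fit SE)
```

and generate starting decks for the four microsolvated species of a new
phenol:

```bash
pkadirect geninput --template --n-waters 2 --functional CAM-B3LYP --solvation SMD
```

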