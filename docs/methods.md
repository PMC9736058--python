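# Methods

## The model

The package computes phenol pKa values by the *direct approach*: the acid
dissociation is written as an isodesmic-style exchange with hydroxide,

    HA·(H2O)n + OH⁻·(H2O)n ⇌ A⁻·(H2O)n + H2O·(H2O)n ,

so one negative ion appears on each side and no solvated proton is needed.
Each species carries the same number n of explicit first-shell waters (0,
1 or 2 in the reference protocol) inside a continuum solvent model. The
reaction *electronic* energy

    ΔE_dep = E(A⁻) + E(H2O) − E(OH⁻) − E(HA)

is converted to a pKa through the affine map

    pKa = ΔE_dep / (ln10·R·T) + C ,   C = 15.74, T = 298.15 K.

Assumptions worth stating plainly:

* **Electronic energies, not Gibbs free energies.** The default pathway
  uses raw SCF energies. The symmetric reaction makes most thermal and
  entropic contributions cancel; `EnergyRecord` accepts an optional
  `free_energy` field, but nothing reads it on the default path.
* **The offset is a constant, never fitted.** C = 15.74 is the molar-scale
  aqueous pKa of water that the hydroxide reference leaves behind. It is
  configurable in `Constants` but the default never changes silently.
* **Hill-slope-1 acid/base behavior** in the titration module: a single
  deprotonation per chromophore.

## Constants and units

| constant | default | unit | note |
| --- | --- | --- | --- |
| R | 1.987204259 × 10⁻³ | kcal·mol⁻¹·K⁻¹ | CODATA |
| T | 298.15 | K | protocol temperature |
| ln10 | 2.302585… | — | full precision; `Constants.truncated_ln10()` gives the literature habit 2.302 (difference < 0.002 pKa at benchmark energies) |
| C | 15.74 | — | protocol offset |
| Hartree → kcal/mol | 627.5095 | — | overridable |

One pKa unit corresponds to ln10·R·T = 1.3643 kcal·mol⁻¹ at 298.15 K, so
the slope of the pKa map is 0.733 per kcal·mol⁻¹.

Species energies enter in Hartree (native QC output) and are converted
once, in `reaction_energy`. Internal pKa values keep full precision;
rounding to two decimals happens only at presentation (CLI output).

## QC plumbing

The parser targets the Gaussian-style text dialect: the **last** SCF
energy line wins (optimizations print one per step), frequency-block order
is preserved, the final coordinate table is read, and convergence is the
normal-termination marker. Other engines connect through the energy-table
CSV (`label,role,n_waters,energy_hartree,source`), which round-trips at
full precision via `repr`.

True-minimum validation (`validate_minimum`) is strict by default: any
frequency below −tol cm⁻¹ (tol = 0) fails, and `assemble_system` refuses
the species. A log without a frequency block returns *unknown* rather than
true or false — a single point makes no claim about curvature — and
unknown species are accepted into assembly. The imaginary-frequency
tolerance is configurable for engines with noisy low modes.

The shorthand basis spelling "6-311G+dp" is normalized to the canonical
"6-311+G(d,p)"; both are accepted. Charges default to 0 for HA/H2O and −1
for A⁻/OH⁻, multiplicity 1 throughout (closed-shell phenols), all
overridable in `ProtocolSpec`. "PCM" is accepted as an alias of IEFPCM.

## Explicit-water placement

Published starting geometries for microsolvated phenols are built by hand;
the placement here is deterministic so results are reproducible:

* **Water 1 (acceptor)**: oxygen on the phenolic O–H axis at H···O = d1
  (default 1.9 Å), hydrogens pointing away from the solute.
* **Water 2 (donor)**: its donating H at O···H = d2 (default 1.9 Å) along
  the in-plane lone-pair direction of the phenolic oxygen, implemented as
  the direction opposite the sum of unit vectors to the oxygen's covalent
  neighbors (for phenol, the bisector of the reflex C–O–H angle).

d1, d2 are restricted to (1.5, 2.5) Å, a window that brackets the
1.77–2.14 Å H-bond lengths found in relaxed closed-cage phenol clusters.
Original solute atoms are never moved (bit-identical coordinates). Clashes
(non-bonded contact < 1.5 Å) trigger a deterministic stagger of the water
orientation; if no stagger resolves it, a `PlacementError` is raised
rather than silently accepting a bad seed structure.

A two-water cage is classified **open** when the second water's oxygen
lies strictly more than 4 Å from the OH group — the nearer of the phenolic
O and H, since "distance from the OH group" has no unique reference point —
and **closed** otherwise; the boundary value is closed. Both topologies
can be constructed (`open_cage=True` parks the second water at 4.5 Å),
because electron-poor phenols (nitro, cyano, sometimes methoxy) prefer
open cages; no automatic rule chooses between them, the caller does.

The phenolate geometry is the acid minus its tagged phenolic H with all
waters kept in place, which makes the elemental balance of
HA + OH⁻ vs A⁻ + H2O exact by construction; `check_atom_balance` verifies
it and reports a per-element diff instead of raising.

## Benchmark statistics

Error conventions (the ones under which the bundled reference statistics
reproduce, and which are *not* universal in the literature):

* ΔpKa = pKa_calc − pKa_exp (signed, calculated minus experimental);
* MAE = mean |ΔpKa|;
* the reported "standard deviation" is the **population** (divide-by-n)
  std of the **absolute** errors — the signed-error std would be ~0.46 on
  the bundled two-water SMD column and the sample-normalized absolute
  version 0.31, neither of which matches the published 0.30;
* the calc-vs-exp regression slope is **through the origin**,
  Σ(ref·calc)/Σ(ref²); ordinary least squares with intercept gives ≈1.16
  on the same data and is exposed separately (`ols_slope`).

The bundled table carries 13 substituted phenols with five protocol
columns. Two internal inconsistencies of the published rendition are kept
in the records' `notes` field rather than corrected: the carvacrol
two-water SMD delta is printed with the wrong sign (+0.06 vs arithmetic
−0.06), and the phenol B3LYP/SMD delta appears as both 0.02 and −0.03
across the source's own tables. Neither affects absolute statistics. The
published headline MAE for the best column is variously given as 0.3,
0.37 and 0.39; recomputation from the per-compound values gives 0.384,
which is what this package reports.

## Titration fitting

`fit_pka` performs unweighted nonlinear least squares of the
Henderson–Hasselbalch sigmoid. Initialization: plateaus from the first and
last absorbance, pKa from the pH nearest the half-height — with at least
five points spanning both sides of the transition this removes
starting-value sensitivity. The quoted uncertainty is the asymptotic ±1
standard error from the fit covariance, labelled as such (it is not a
replicate spread).

Degenerate-input guard: the transition amplitude is measured on a 5-point
moving average (so uncorrelated noise cannot fake a span) and compared to
a noise scale estimated from second differences; amplitude below 5× noise
raises `DegenerateCurveError` instead of returning a meaningless fit.

## Synthetic data

`fixtures.make_energy_set` inverts the pKa map: three species energies are
drawn near realistic anchors (HA ≈ −308 Ha, OH⁻ ≈ −75.9 Ha, H2O ≈ −76.45
Ha, seeded milli-Hartree jitter) and the fourth is solved so the reaction
energy reproduces the target pKa. Using hundreds-of-Hartree magnitudes
means the round trip exercises exactly the catastrophic-cancellation
regime real data live in; recovery is ~10⁻¹¹ pKa, bounded in tests at
10⁻⁹. Mock logs cover every parser branch (with/without frequencies,
converged or not, multiple SCF lines, truncated tables).

What the generator does **not** emulate: real electronic structure (the
mock energies have no physics beyond their sums), conformer diversity,
engine-specific log quirks beyond the Gaussian-style dialect, correlated
baseline drift in titration curves. Passing tests therefore demonstrate
correctness of the thermodynamic algebra, the statistics, the geometry
rules and the fitting — not the accuracy of any DFT protocol, which only
the external engine can supply.

## Problem sizes and determinism

The test suite and the acceptance script use 100-target round trips, 100
seeded titration replicates per pKa, and the 13-compound benchmark —
seconds of runtime in total. All randomness flows through
`numpy.random.default_rng` with explicit seeds; property tests run
hypothesis derandomized. CLI exit codes: 0 success, 2 schema/config
error, 3 protocol violation, 4 fit failure.

## Known limitations

* The placement rules produce chemically sensible *starting* points, not
  optimized clusters; reproducing relaxed geometries requires the QC
  engine.
* Only single deprotonations are modelled; polyprotic acids and
  intramolecularly H-bonded (ortho-substituted EWG) phenols are outside
  the validated envelope.
* The parser reads one calculation per file; multi-job archives and
  checkpoint/binary formats are out of scope.
* Whether published benchmark energies included thermal corrections is
  not determinable from the printed data; the default here is raw
  electronic energy, and the choice is explicit in `core_thermo`.
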