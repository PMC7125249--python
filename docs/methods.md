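# Methods

## Model

The package treats a solute as a discrete ensemble of microstates
(tautomers) *t*, each with conformations *c*, in a given solvent. The input
per state is a set of precomputed energy components: the electronic energy
in solution `E_sol`, the uncorrected excess chemical potential `mu_ex` and
partial molar volume `V_m` from 3D RISM, the gas-phase electronic energy
`E_vac` for vacuum reference conformations, and the molecular net charge
`q` (a molecular property, constant across states). All energies are
kcal/mol, volumes Å³, charges in units of e; there is no unit-conversion
layer.

The per-state Gibbs energy is

    G_tc = E_sol + c_mu * mu_ex + c_V * V_m + c_q * q

where the linear correction compensates the known error of 3D RISM excess
chemical potentials, which scales with the partial molar volume. Entropic
contributions from rotational and vibrational degrees of freedom are
deliberately ignored: the ensemble entropy enters only through the discrete
partition functions

    G_t = -RT ln sum_c exp(-G_tc / RT)          (conformers)
    G   = -RT ln sum_t exp(-G_t  / RT)          (tautomers)

Solvation Gibbs energies subtract a gas-phase reference,
`dGsolv = G_solution - G_vacuum`, where the vacuum partition function pools
*all* gas-phase conformers of all tautomers into a single sum. This pooled
convention matters: the training loss (below) is written with one gas-phase
sum per molecule, and the gas-phase conformer set need not coincide with
the solution-phase one. A per-tautomer vacuum reference would be a
different (also defensible) model; the pooled one is what this package
implements throughout, so training and prediction are mutually consistent.

The decadic partition coefficient follows from the water→octanol transfer
Gibbs energy,

    log P = (G_wat - G_oct) / (RT ln 10).

Because the gas-phase terms cancel in the thermodynamic cycle, log P is
computed directly from the *absolute* solution-phase Gibbs energies; the
solvation free energy route exists separately for training and for
databases that tabulate per-phase dGsolv. Positive log P means preference
for octanol. Only neutral species are exercised by the shipped presets
(`q = 0`); the `c_q` term is carried for API completeness and for training
sets that do contain ions.

## Parameters

| parameter | units | meaning | shipped values |
| --- | --- | --- | --- |
| `c_mu` | – | scaling of the excess chemical potential | 1 (water, fixed; 1-par octanol models), 1.33446 (dry 2-par), 1.28924 (wet 2-par) |
| `c_V` | kcal mol⁻¹ Å⁻³ | PMV correction slope | −0.10251 (water), −0.00799 / −0.00609 (dry 1-/2-par), −0.01552 / −0.01315 (wet 1-/2-par) |
| `c_q` | kcal mol⁻¹ e⁻¹ | net-charge term | −15.728 (water), 0 (octanol) |
| `T` | K | temperature | 298.15 |
| `R` | kcal mol⁻¹ K⁻¹ | gas constant | 1.98720425864083×10⁻³ (CODATA) |

The source tables state `T` but not the value of `R` used; the CODATA value
is adopted and both `R` and `T` are overridable through `ThermoConstants`,
which is threaded through every Boltzmann sum (tests exercise temperatures
down to 10⁻³ K). "Dry" octanol is pure n-octanol; "wet" is water-saturated
n-octanol (water mole fraction ≈ 0.27). The 1-parameter octanol models fix
`c_mu = 1` exactly and fit only `c_V`; 2-parameter models fit both.
`free_mask` on `CorrectionParams` records the fixed/fitted structure, and
fixed coefficients keep their preset values through training.

The shipped octanol presets were trained externally on the Minnesota
Solvation Database (224 molecules with experimental n-octanol solvation
Gibbs energies); that database and the per-molecule component energies are
not redistributable here, so re-deriving the presets is an optional
validation path for users who hold the data (`pmvlogp train` on their
tables), not a shipped computation.

## Training

The loss is the sum over molecules of squared deviations between
partition-function solvation Gibbs energies and experiment:

    L(c) = sum_m ( dGsolv_model(m; c) - dGsolv_exp(m) )^2 .

Since the free coefficients occur inside the exponents, `L` is nonlinear
whenever any molecule has more than one state; with exactly one state per
molecule it collapses to ordinary least squares, which the test suite uses
as a closed-form oracle (agreement to 10⁻⁸).

Numerical choices:

- **Optimizer**: derivative-free Nelder–Mead, run from every point of a
  small multi-start grid (`c_mu ∈ {0.5, 1, 1.5}` × `c_V ∈ {0, −0.01, −0.1}`,
  plus `c_q ∈ {0, −15}` when fitted), keeping the best local minimum.
  Tolerances 10⁻¹⁰ on the loss and 10⁻⁸ on parameters; deterministic for
  fixed settings.
- **Degeneracy guard**: if any *free* coefficient multiplies a data column
  that is identically zero (e.g. all `mu_ex = 0`), the loss is flat along
  that coordinate and the fit aborts with `DegenerateDataError` rather than
  returning an arbitrary point.
- **Coverage**: every molecule needs at least one solution state, one
  vacuum state and an experimental value; in strict mode a missing value is
  an error, in permissive mode the molecule is dropped with a logged count.
- **Bootstrap**: molecule-level resampling with replacement; each resample
  is re-fit warm-started at the full-data estimate (a single simplex start —
  resamples are small perturbations of the full problem, and the warm start
  keeps hundreds of refits cheap). Percentile intervals at 95% by default;
  resamples with fewer distinct molecules than free parameters are skipped
  with a warning. At least 100 resamples are recommended; the implementation
  enforces only ≥ 1 so cheap smoke tests remain possible.

## Numerical notes

- All partition functions use max-shifted log-sum-exp
  (`scipy.special.logsumexp`, or an equivalent segmented shift inside the
  vectorized training loss). Absolute electronic energies of order
  10²–10⁵ kcal/mol make naive exponentiation overflow immediately; the
  shifted form is exact for a single state and agrees with direct summation
  to 10⁻¹⁰ relative at moderate magnitudes (property-tested).
- The aggregate is always ≤ the minimum input energy, adding a state never
  raises it, `T → 0⁺` recovers the minimum, and a uniform energy shift Δ
  shifts the aggregate by exactly Δ. For fixed `q` the `c_q` term is such a
  uniform shift, so it can never change conformer or tautomer weights.
- Tautomer Boltzmann weights are computed with a shift-invariant softmax
  and sum to 1 within 10⁻¹².
- Tabular round trips are lossless: floats are written with 17 significant
  digits and parsed with correctly-rounded (`round_trip`) conversion. An
  empty cell means "absent"; zero is a value.
- Reported statistics are compared to printed reference values with
  half-away-from-zero rounding at the printed decimals; full-precision
  values are always exposed alongside.

## Evaluation conventions

- "MSE" in the challenge-statistics sense is the **mean signed error**
  (predicted − experimental; underprediction is negative). The API calls it
  `mean_signed_error` to avoid collision with mean squared error.
- The descriptive regression is OLS of *predicted on experimental* (the
  orientation of the standard predicted-vs-experimental scatter plot), and
  R² is the squared Pearson correlation.
- `leave_one_out_impact` reports, per molecule, the RMSE of the remaining
  n−1 pairs and the drop relative to the full-set RMSE, sorted so the
  dominant outlier comes first.
- `group_error_decomposition` summarizes per-molecule signed errors by
  compound class and solvent (mean, median, water-minus-octanol
  difference), with molecules ordered ascending by octanol error within
  class.

## Tautomer rank concordance

`rank_shift_report` compares the stability ordering of a molecule's
microstates across solvent/model columns. Orderings are compared over the
*thermally resolvable* microstates — those whose Boltzmann population
reaches `min_population` (default 10⁻⁶) in at least one column. The
ordering of states whose populations vanish in every environment (relative
energies ≳ 8 kcal/mol at 298 K) carries no observable content and sits far
below the accuracy of the underlying energies, so it is excluded by
default; `min_population=0` performs the strict full-ordering comparison
instead. On the shipped reference table the default finds no rank change in
any compound, while the strict mode flags exactly one inversion — between
the 2nd and 3rd microstates of SM16 (relative energies 11–14 kcal/mol,
populations < 10⁻⁹) when moving from the 2-parameter to the 1-parameter
octanol columns — illustrating why the population filter is the meaningful
default. Ties in the ordering are broken lexicographically by microstate
label and the reference data contain none.

Conformer-to-microstate reassignment (for conformations whose protonation
topology changed during upstream structure optimization) is explicit user
input — a `(molecule, conformer, phase) → microstate` mapping file — never
automatic structure perception; the operation is idempotent and validates
that every target microstate exists.

## Synthetic data generator

`generate_dataset(SyntheticSpec(...))` emulates the *shape* of EC-RISM
component tables with a fully known answer:

- 200 molecules by default, 1–3 tautomers each, 1–5 conformers per
  tautomer and phase (gas-phase conformer sets drawn independently of the
  solution ones), all neutral.
- `V_m ~ U(50, 400)` Å³ with small per-state jitter; `mu_ex` linear in
  `V_m` with negative slope (−0.11 kcal mol⁻¹ Å⁻³, intercept 5.5) plus
  molecule-level (σ = 2) and state-level (σ = 0.5) Gaussian noise, covering
  roughly [−40, 5] kcal/mol.
- Base electronic energies `U(−10⁵, −10⁴)` kcal/mol so the numerical
  stability paths are genuinely exercised; tautomer gaps `U(2, 12)`
  kcal/mol; conformer spreads exponential with mean 1 kcal/mol.
- True correction parameters: the water preset for water and
  `c_mu = 1.3, c_V = −0.01` for wet octanol.
- Noiseless observables (dGsolv per solvent, log P) are computed through
  the package's own forward model under the true parameters, then perturbed
  with additive Gaussian noise (σ = 0.3 kcal/mol by default); the
  experimental log P is derived from the noisy per-phase dGsolv values so
  the experiment table is internally consistent.
- All randomness flows from one seeded `numpy` generator; identical specs
  give bit-identical datasets, and the spec is serialized next to every
  written dataset.

`generate_outlier_scenario` additionally shifts the experimental water
values of a labeled molecule subset by a constant, producing a class-wise
systematic water-vs-octanol error (and the corresponding `offset/(RT ln10)`
log P error) for testing the outlier and group-decomposition analyses.

What passing tests on this generator do and do not show: they verify the
estimator (parameter recovery is unbiased within Monte-Carlo error at
n = 200, σ = 0.3, and the recovery error shrinks from n = 50 to n = 500),
the thermodynamic identities, and the analysis pipeline — but the generator
makes no attempt to reproduce real quantum-chemical energy surfaces,
RISM correlation-function physics, correlated experimental errors, or the
chemical-class structure of real training databases, so success here does
not by itself certify accuracy on real compounds.

## Problem sizes and determinism

The shipped test suite and the acceptance script run on the packaged
11-compound reference tables (sub-second) and on seeded synthetic datasets
of 25–500 molecules with 20 replicates for the recovery study — sizes at
which the simplex fit takes well under a second each, keeping the whole
suite around a minute while still separating estimation noise from bias.
Hypothesis-based property tests run derandomized; every stochastic
computation takes an explicit integer seed.

## Known limitations

- No ionic species or pH-dependent log D; `c_q` is carried but all shipped
  presets are exercised at `q = 0`.
- The pooled-vacuum convention is a modeling choice (see above); users
  whose upstream pipeline defines per-tautomer gas-phase references must
  pre-aggregate accordingly.
- No regularization or cross-validation in training — the models are plain
  least squares with 1–3 parameters by design.
- The package never sees molecular structures: reassignment, class labels
  and state tables are the user's responsibility, and no structure-derived
  sanity checks are possible.
- Trained preset values are reproducible only with the external training
  database; within this package they are authoritative constants.
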