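# Methods

## The equilibrium model

A pool of RAF protomers (total concentration `[RAF]`, µM) is treated at
thermodynamic equilibrium with a RAF inhibitor at free concentration `D`.
Seven species are tracked: autoinhibited monomer `A`, open (non-autoinhibited)
monomer `R`, drug-bound monomer `RD`, and dimers with zero/one/two drugs
bound (`R2`, `R2D`, `R2D2`), plus free drug. Only the open form can dimerize
or bind drug, and a drug-bound protomer cannot return to the autoinhibited
state without first releasing its drug. Wild-type RAF is implicitly
RAS-GTP-engaged; "active RAF" is every protomer that sits in a dimer and is
not itself drug-bound (a singly drugged dimer still carries one active
protomer).

Pairwise equilibria, with explicit statistical factors:

| step | constant | note |
|---|---|---|
| `A ⇌ R` | `K_A = [A]/[R]` | autoinhibition, dimensionless |
| `R + D ⇌ RD` | `K_d` | drug on open monomer |
| `R + R ⇌ R2` | `K_dim` | drug-free dimer |
| `R2 + D ⇌ R2D` | `f·K_d` per site, weight 2 | first drug on a dimer |
| `R2D + D ⇌ R2D2` | `g·K_d` per site, weight ½ | second drug |

Detailed balance (every closed reaction cycle has an equilibrium-constant
product of one) then forces the remaining assembly routes: `R + RD ⇌ R2D`
at `f·K_dim` and `RD + RD ⇌ R2D2` at `f·g·K_dim`. One factor of `f` is
carried per drug-containing dimer (not per bound drug): `f` simultaneously
describes the enhanced drug affinity of a dimer site and the enhanced
dimerization of drug-bound monomers — these are the same physical statement
once cycles must close. `g` penalizes only the second binding event. The
resulting dimer occupancy weights relative to `R²/K_dim` are
`1 : 2d/f : d²/(f·g)` with `d = D/K_d`.

Variants pin the mechanisms they exclude: CA (`f = g = 1`), DP
(`K_A = 0, g = 1`), NC (`K_A = 0, f = 1`); the unified model frees all
three. The variant is an explicit enum — `f = 1` inside a unified fit is a
legal estimate, not a variant switch.

### Closed forms

Protomer conservation reduces to a quadratic in `R`; all observables are
rational functions of its positive root. With `E1 = 1 + K_A + d`,
`E2u = 8·RAF_rel·(fg + 2gd + d²)/(fg)`, `RAF_rel = [RAF]/K_dim`:

* baseline active fraction: `E3/(1 + √(1+E3))²`, `E3 = 8·RAF_rel/(1+K_A)²`
  (DP/NC: the same with `K_A = 0`),
* active fraction: `X²·g(f+d) / (E2u·(fg + 2gd + d²))`,
  `X = −E1 + √(E1² + E2u)`,
* dimers per active protomer: `(fg + 2gd + d²)/(2g(f+d))` — ½ at `d = 0`
  (each drug-free dimer carries two active protomers) and growing with dose.

`X` is evaluated as `E2u/(E1 + √(E1²+E2u))` to avoid cancellation; the
closed forms hold to ~1e-15 relative against the oracle across the full
fitting domain (bounds below), including `RAF_rel` up to 10⁷ and `d` up to
10⁶. Square-root arguments are asserted nonnegative (tolerance 1e-12) and
violations raise rather than clamp — a domain error would indicate a
transcription bug, never a legitimate state.

### The oracle

`rafpa.oracle` is deliberately ignorant of the closed forms: it propagates
the pairwise equilibria from `(R, D)`, checks cycle closure at a reference
state (relative tolerance 1e-10), and solves protomer conservation — a
strictly increasing scalar function of `R` bracketed by `(0, [RAF]]` — with
Brent's method at machine-precision relative tolerance. The buffered-drug
mode (dose = free drug) matches the closed forms' single free variable and
is the mode all validation uses; a conserved-total-drug mode (nested
bracketing over free `D`) is provided as an extension for cases where drug
depletion by binding matters.

## PA metrics and conditions

The baseline is the activity at dose zero (every dose grid contains 0).
The peak is the grid maximum refined by bounded golden-section search
between its bracketing grid points (dose resolved to 1e-4 relative);
activity comparisons use a 1e-9 absolute tolerance, far below biological
meaning and far above solver noise. PA range endpoints are located by
bisection on `activity(d) − baseline`; the upper endpoint is a baseline
re-crossing, which makes the range robust to monotone transformations of
the readout (unlike the fold change, which saturating downstream reporters
can distort). Dose grids are logarithmic, 25 points/decade by default.

Analytic PA conditions, resolved from the equilibrium algebra and verified
against numerical scans:

* **CA** (necessary and sufficient): `RAF_rel < (1 + 3K_A)(K_A − 1)/8`.
  PA requires the autoinhibited form to be favored (`K_A > 1`) and RAF
  scarce relative to `K_dim`.
* **DP** (sufficient): `f < ½` and `8·RAF_rel < (1 − 2f)(3 − 2f)`.
* **NC**: no PA possible.
* **unified** (sufficient): `g ≥ 1`, `2f < 1 + K_A` and
  `8·RAF_rel < (1 + K_A − 2f)(3(1 + K_A) − 2f)`; collapses to the CA
  condition at `f = g = 1` and the DP condition at `K_A = 0`.

Sufficient-only predicates return an explicit *indeterminate* (not
`False`) when the inequality fails, so a caller cannot mistake "condition
not met" for "no PA". Numerical scans (100 × 100 grid for CA; random
draws for DP/unified) found no counterexamples to any predicate.

## Fitting

The inverse problem follows the structure of a cell-line inhibitor panel:
a drugs × doses matrix of max-normalized active-RAF readouts, one shared
autoinhibition constant `K_A` (a property of the cell), per-drug
`(K_d, f, g)`, and fixed `[RAF] = 0.04 µM`, `K_dim = 0.1 µM` (freeing them
creates a known ridge, see below). Predictions are normalized exactly as
the data are — per-drug maximum — before any metric is evaluated. Metrics
(balanced panels; the mean runs over all drugs × doses jointly):

* `chisq` — mean of `((y_pred − y_obs)/y_obs)²` (the fitting objective),
* `absolute` — mean of `|y_pred − y_obs|/y_obs`; ×100 it is the "mean
  percentage error" used for sub-model comparison.

Optimization is over log10-transformed parameters (the bounds span
decades: `f ∈ [1e-5, 1e2]`, `g ∈ [1, 1e4]`, `K_A ∈ [1e-3, 1e2]`,
`K_d, K_dim ∈ [1e-4, 1e4] µM`, `[RAF] ∈ [1e-4, 1e3] µM`). Each of the
(default 100; 1500 is the thorough setting) log-uniform random starts runs

1. a joint bounded SLSQP solve (ftol 1e-10),
2. a block-coordinate rescue: given the globals, the metric decomposes
   over drug rows, so each drug's own 2–3 parameters are refit from a few
   fresh log-uniform starts — this reliably frees single drugs stranded in
   wrong local basins, which pure joint descent from random starts leaves
   behind at this start count,
3. a final joint SLSQP polish to a stationary point.

Failures of individual starts are skipped, not fatal. The reported
ensemble is every completed solution within 10% of the lowest metric;
everything is reproducible from the seed. Sub-model comparison re-runs the
identical protocol with mechanisms pinned (`g ≡ 1`, `f ≡ 1`, `K_A ≡ 0`,
and two-mechanism exclusions), optimizing the absolute metric. The
identifiability report gives per-parameter ensemble ranges and CVs and
flags pairs with `|Pearson r| > 0.9` on log-scaled ensemble values; with
`K_dim` and `K_A` both free the two sit on a ridge (baseline activity
depends on them mainly through `K_dim·(1 + K_A)²`), which the report
flags.

## Synthetic panels

The generator emulates the design of a nine-inhibitor, seven-dose,
63-point normalized panel. Per-drug parameters are log-uniform within
archetype ranges chosen as package constants (they are design choices, not
measured values): type I `f ∈ [0.01, 0.05]`, `K_d ∈ [2e-3, 2e-2] µM`
(strong potentiation, potent binding); type I.5 `f ∈ [0.1, 0.4]`,
`K_d ∈ [0.1, 1] µM`; type II `f ∈ [0.7, 1.4]`, `K_d ∈ [5e-3, 5e-2] µM`
(little potentiation). The non-overlapping `f` ranges encode the
type I < I.5 < II ordering. Negative cooperativity is strong for every
class (`g ∈ [100, 1000]`): with `g` in the hundreds the high-dose fall of
each curve is governed by monomer capture at `K_d`, which keeps `K_d` and
`f` identifiable from a seven-point curve while leaving `g` itself weakly
constrained — the expected outcome for this readout. Shared cellular
context: `K_A = 10`, `K_dim = 0.1 µM`, `[RAF] = 0.04 µM`. The seven doses
span 10 pM–10 µM (decade spacing) so that every archetype's identifying
features — the rise near `f·K_d` and the fall near `K_d` — lie inside the
sampled window; with narrower windows those features leave the data and
the affected parameters become structurally unidentifiable (only `f·K_d`
is then determined).

Noise is mean-one multiplicative log-normal (`σ² = log(1 + cv²)`), default
CV 5%, applied to the raw activities before per-drug max-normalization —
the order in which real normalized band intensities are produced. What the
generator does **not** emulate: blot image formation and densitometry
nonlinearity, dose-measurement error, correlated (batch) noise, multiple
RAF paralogs, or any downstream signal transformation. Passing recovery
tests therefore demonstrate that the *inference machinery* is correct and
well-posed under the stated statistical model, not that real lysate data
would constrain the parameters equally well.

## Numerical and design choices

* Drug is buffered: the dose axis is free drug, matching the closed
  forms' single free variable; the conserved-drug oracle mode exists for
  sensitivity checks.
* Root solving uses bracketing (Brent) exclusively — monotone scalar
  reductions with guaranteed convergence — never multidimensional Newton.
* The ensemble window (10% of the minimum metric) is applied to the
  metric value, not to parameter distance; ties inherit stable ordering.
* Degenerate inputs: empty grids, grids missing dose 0, negative doses,
  non-positive observations, and zero-activity dimer ratios all raise
  with explicit messages.
* Problem sizes in the validation pipeline (1000 oracle parameter sets,
  10⁴ NC draws, 100 × 100 condition scan, 100-start fits on the 9 × 7
  panel) were chosen to keep the full validation run in the tens of
  minutes on a single core while leaving each check statistically
  comfortable.

## Known limitations

* Equilibrium only: no kinetics, no pathway dynamics, no account of slow
  drug binding or cellular turnover.
* The active-RAF readout is linear in protomer counts; saturating
  reporters downstream will compress fold changes (PA range is the more
  robust observable).
* The per-drug `g` is reported but should not be over-interpreted: it is
  weakly constrained by 7-point single-readout curves, and in real data
  it may absorb mechanisms the model omits.
* Sub-model comparison uses best-fit error only; it is a descriptive
  ranking, not a complexity-penalized model selection.
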