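# Methods

`reactoprobe` analyses ensembles of steered Born–Oppenheimer molecular-
dynamics (BOMD) trajectories in which an external bias extracts the acidic
α-hydrogen of a nitroacetamide solute into the surrounding water bath, and
turns the ensemble statistics into an estimate of the compound's pKa shift
against a reference compound.  It also implements the potentiometric-
titration analysis used to measure the same shift experimentally, so the two
routes can be compared on equal footing.  This note records the models, the
parameters that matter, the synthetic-data recipe, and the numerical and
design choices.

## The steering experiment being analysed

The collective variable is a smooth coordination number between the
α-carbon and its two α-hydrogens,

    CN = Σ_{i,j} s(r_ij),     s(r) = (1 − x⁶)/(1 − x¹²),   x = (r − d0)/σ,

with `s = 1` for `r ≤ d0`.  The rational form has a removable singularity at
`x = 1`; since `(1 − x⁶)/(1 − x¹²) = 1/(1 + x⁶)` for all `x > 0`, the
package evaluates the latter everywhere (`cv_bias.switching_value`).
Defaults are `d0 = 1.1 Å`, `σ = 0.5 Å`.

The bias is a moving harmonic restraint `U_e = (k/2)(CN − CN0(t))²` with
`k = 1250 kcal/mol = 5230 kJ/mol`.  The forward protocol ramps `CN0`
linearly from 2 to 1 at 1 CN per 2 ps after 1 ps of unbiased equilibration
(the ramp shape is taken linear — the protocol fixes only the rate, and a
constant-rate moving restraint is standard practice).  The backward
protocol counts protons on all water oxygens instead, ramps
`2·n_waters + 1 → 2·n_waters` at the same rate, uses `d0 = 0.98 Å` (the
equilibrium O–H distance in water) and a force constant reduced 100-fold.
The package only *scores* trajectories against these schedules; it never
integrates equations of motion.

## Trajectory classification

Each run is labelled `fault`, `reactive` or `non_reactive`, in that
precedence order:

* **fault** — the electronic structure left the ground state and the energy
  diverged.  Declared when any logged energy is non-finite, or when the
  rolling 50-point mean of U ends the run more than 10 baseline standard
  deviations from the pre-bias mean *and* is still growing (final drift at
  least 2× the drift 250 fs earlier, or the band crossed only within that
  lag).  The growth qualifier is essential: a genuine reactive event leaves
  a *bounded* product-state energy offset that can itself exceed 10 σ of a
  quiet baseline, while ground-state breakdown grows without bound.  A
  bounded step in the last ~0.25 ps of a run would still be mistaken for a
  divergence; with reaction times occurring mid-ramp this corner does not
  arise in practice.
* **reactive** — CN crosses below 1.5 (the reactant/product midpoint) and
  stays below it to the end of the run for at least 0.1 ps.  The real
  transition is fs-scale, so the 0.1 ps hold rejects transient dips at no
  risk of missing true events; the reaction time is the first point of the
  sustained excursion.
* **non_reactive** — everything else.

Faults are excluded from every downstream statistic.  The chemical final
state of a reactive run is read from geometry: the extracted proton's
nearest tagged heavy atom within a covalent cutoff (1.3 Å for C–H, 1.2 Å
for O–H/N–H) maps to nitro (α-carbon), aci (nitro oxygen), enol (carbonyl
oxygen) or nitronate (water oxygen).

## The scaled-energy pKa estimator

The reaction's energy signature is buried in equilibrium fluctuations of
the total potential energy.  The estimator (module `energetics`):

1. removes the equipartition baseline `U_vib = N_deg·R·T(t)/2` with
   `N_deg = 3·N_a − 6`, scales by `N_deg·R·T(t)`, and anchors each
   trajectory at the bias start `t0`:
   `U′(t) = [U(t) − U_vib(t)]/(N_deg·R·T(t)) − U′(t0)`.
   The instantaneous logged temperature is used by default (an option for a
   thermostat set-point exists); the anchoring makes U′ invariant under any
   constant energy offset;
2. averages U′(t) separately over the reactive and non-reactive classes,
   with per-time RMSD bands;
3. forms the reactive ratio `x_p = n_react/(n_react + n_nonreact)` and
   `ΔU′ = x_p · ⟨U′_p(t) − U′_r(t)⟩ · N_deg`, the time average running over
   the last 200 points of the class-mean difference (the late-time window
   where the gap is stable; the window is a parameter);
4. converts to a pKa shift against a reference compound:
   `ΔpKa = (ΔU′_X − ΔU′_ref)/ln 10`.

The class-mean curves are differenced first and then time-averaged —
classes are *not* population-weighted per time point, matching the
class-average construction of the source protocol.  `x_p` is carried at
full precision; printed comparisons round to two decimals.

Internal units are fixed package-wide — Å, fs, K, kJ/mol — with
`R = 8.31446×10⁻³ kJ/(mol·K)`, so the scaling step is dimensionless with no
per-call unit flags.  Scalar logs declare their energy unit in the header
(`units=hartree_per_cell`, `ev`, `kcal_per_mol`, ...) and are converted on
ingest (1 Ha/cell ≡ 2625.4996 kJ/mol).

## Titration analysis

Per-point pKa follows the partial-neutralization relation
`pKa = pH + log10([HA]/[A⁻])` with the ratio fixed by stoichiometry,
`(n₀ − n_b)/n_b`.  Data sheets sometimes print only the *magnitude* of the
log ratio; the reader assigns the sign from the stoichiometric position
(negative past half-neutralization) using the initial volume `v0`, and when
`v0` is unrecorded it is back-solved by least squares from the printed
magnitudes (the fit residual is reported; on the bundled compound-3 sheet
it is 2×10⁻⁴ log units at v0 = 4.31 mL).  Sheets that print signed values
are used as-is.  Of note: the bundled compound-2 sheet's thirteen rows
average to pKa 4.80 while the accompanying summary quotes 4.76; both values
are surfaced and the discrepancy is asserted in the tests rather than
resolved.

Model curves for mono-/bi-/tri-protic acids solve the full charge balance
of HₙA plus strong base and water autoionization by bracketed root search
on pH ∈ [0, 14] (`brentq`, residual tolerance 1e-12; a grid-scan oracle
cross-checks to 1e-3 pH).  Ideal solutions are assumed and Kw is fixed at
1e-14 — the measurements were taken at 23 °C, but the concentration-based
relation above carries no activity or Kw correction, so none is invented.
Dilution by the titrant volume is included.  The second and third
dissociation constants are exposed as parameters only (the reference
analysis set them by manual curve comparison, not optimization).

## Structural analyses

Hydrogen bonds use the geometric criterion d(X,Y) ≤ 3.5 Å and angle ≤ 30°,
with the angle taken at the donor heavy atom (the Y−X−H angle, following
the stated letter order); the common alternative that places the cone at
the hydrogen is available as an option.  Donor–H covalency is supplied by
topology once at load time (element + 1.2 Å cutoff), not re-perceived per
frame — important for stability while bonds are actually breaking.

g(r) is the observed minimum-image pair-distance density over the
ideal-gas expectation at the same pair density, normalized per frame with
the instantaneous cell volume, so a uniform sample gives g ≡ 1;
`r_max ≤ min(cell)/2` is enforced.  Long-range deviations of g(r) from 1
in product-state windows (a real effect of bulk-water destabilization in
small cells) are reported, not corrected.  Distance series report
per-frame minimum-image distances, below-threshold event counts (default
4.5 Å, the molecular-compaction criterion) and windowed mean ± sd.
Analysis windows are user-supplied (product-state defaults to the final
0.5 ps of a run).

## Synthetic study inputs

The generator's defaults *are* the study conditions: 100 trajectories,
1268 atoms (416 waters + a 20-atom solute), 3 ps at 1 fs logging, bias
start at 1 ps.

* **Conformer walk** — every rotatable dihedral is rotated by an
  independent uniform angle per step; the move passes a Metropolis test on
  a pairwise repulsive clash score Σ (σ_ij/r)¹² (σ from van der Waals
  radii, over pairs ≥ 3 bonds apart) at a per-step temperature drawn
  log-uniformly from [10⁻³, 10⁴] K.  A uniform draw over seven decades
  would collapse onto the top decade, so the log-uniform reading of
  "random temperature in a range" is adopted.  Rigid rotations preserve
  all bonded internal coordinates exactly.
* **Water shells** — waters with O within the shell radius (15 Å) of any
  solute atom are kept, those closer than 1.2 Å to the solute dropped;
  samples short of the common target re-extract with a 2% larger radius
  (growing, never inserting molecules), and the excess elsewhere is
  randomly deleted so every sample carries the same water count.  The bulk
  box is a jittered cubic lattice of rigid waters at 0.976 g/cm³ — a
  geometric stand-in adequate for counting and leveling, with no claim to
  liquid structure.  The 20-atom solute is embedded from connectivity
  (distance geometry via RDKit) and is likewise a synthetic stand-in.
* **Mock steered ensembles** — per trajectory: T(t) = 300 K + 100 K ·
  sin(2πt/2 ps + φ) with random phase (the ~200 K peak-to-peak slow
  oscillation of small-cell deterministic thermostats); U(t) =
  N_deg·R·T/2 plus AR(1) noise (correlation time 50 fs, stationary sd
  10 kJ/mol); reactive runs get a fs-scale CN sigmoid 2 → 1 at a reaction
  time uniform in 1.5–2.5 ps and a sustained product offset
  δ·N_deg·R·T(t); fault runs diverge exponentially (e-folding 30 fs).
  The noise sd is chosen once so the across-trajectory U′ bands are a few
  percent of the per-degree product offset (δ = −0.0267 for the
  reference-compound conditions) — visible bands, resolvable estimator.
  All randomness derives from one integer seed through `SeedSequence`
  spawning, so every sub-generator is independently reproducible.

What the mock does *not* emulate: real solvent dynamics, hydrogen-bond
network rearrangement, any coupling between CN and the energy beyond the
injected offset, or thermostat physics beyond the phase-random sinusoid.
Passing recovery tests therefore demonstrate that the *estimator pipeline*
is unbiased and correctly implemented under the stated statistical model —
not that the underlying MD observables are reproduced.

## Verification strategy and problem sizes

Engine-scale runs (100 × 3 ps × ~7 h each) are out of reach, so the test
suite (i) reproduces every printed-arithmetic result of the reference
tables exactly — all 23 per-point pKa rows, the sheet means, the reactive
ratios, the ΔU′ → ΔpKa chain, the water-box density; (ii) checks each
geometric/numeric kernel against an independent brute-force oracle
(pair-sum CN, triple-loop hydrogen bonds, 27-image minimum-image
enumeration, pH grid scan) on ≥ 100 random instances; and (iii) runs
parameter recovery on 100-trajectory mocks sized to the published summary
numbers, requiring exact label recovery and the injected ΔpKa within 15%
relative error.  Ideal-gas RDF nulls use 4 frames × 500 particles.  These
sizes keep the whole suite around a minute on one core while leaving every
statistical bound comfortably resolvable.

## Known limitations

* Orthorhombic cells only; no binary trajectory formats; no velocities.
* The fault rule sees only logged scalars — no electronic-structure
  diagnostics — and cannot distinguish a bounded step occurring in the
  final quarter-picosecond from a divergence.
* The titration model ignores activity coefficients and electrode
  calibration; pKa₂/pKa₃ are inputs, never fitted.
* Back-solved v0 assumes the printed ratio column is internally consistent
  with a single initial volume.
* The conformer walk's clash score is a declared stand-in for a physical
  repulsion; it rejects overlaps but has no attractive terms, so the walk
  samples sterically-allowed, not Boltzmann-weighted, conformers.
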