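# Methods

## The model

`knotbridge` simulates a ring of `N` beads `r_0 .. r_{N-1}` (periodic,
`r_N = r_0`) with the quadratic semiflexible-Gaussian potential, in units of
`kB T`:

    U = sum_n  3/(2 a^2) |r_{n+1} - r_n|^2  +  K/2 |r_{n+1} - 2 r_n + r_{n-1}|^2

The first term is entropic (Gaussian) bond elasticity, the second a
mean-field bending rigidity.  Bond lengths are not fixed — this is what makes
the model exactly solvable, and also why the contour length fluctuates during
dynamics (reports can rescale it; the dynamics itself never does).

Units: the target root-mean-square bond length `b` is the unit of length and
`b^2/D` the unit of time, with `D = 1` the bead diffusion coefficient and
`kB T = 1` (friction `gamma = 1/D`).

### Calibration of (a, K)

Write `kappa = K a^2/3` and `w_p = 2 pi p / N`.  The equilibrium (Boltzmann)
statistics of U give exactly

* `<|u|^2> = a^2 S(kappa, N)`, with
  `S = (1/N) sum_{p=1}^{N-1} [1 + 2 kappa (1 - cos w_p)]^{-1}`.
  The `p = 0` centre-of-mass mode carries no bond content and is excluded —
  at the default stiffness its inclusion would bias the bond calibration by
  about 4%, visible in the equilibrium tests.
* bond-direction correlations `<u_n . u_{n+s}> / <|u|^2> = A z^s + offset`,
  with `z = exp(-mu)` and `cosh(mu) = 1 + 1/(2 kappa)` (an exact pole
  condition of the discrete propagator).  The decay length is therefore
  `sqrt(kappa)` bonds for stiff chains, *not* `kappa` bonds: the bending term
  couples neighbouring bonds harmonically, and the extensibility of the
  bonds softens orientational memory relative to an inextensible worm-like
  chain with the same bare rigidity.

Given targets `(b, lP)` the package therefore solves, in closed form,

    kappa = 1 / (2 (cosh(b/lP) - 1))   (~ (lP/b)^2 for lP >> b)
    a     = b / sqrt(S(kappa, N))
    K     = 3 kappa / a^2

so that the *measured* persistence length of equilibrium samples equals the
requested `lP`.  A frequently quoted shortcut identifies `lP/b` with `kappa`
itself; for this model that identification fails the direct test (the
tangent-correlation decay of samples calibrated that way comes out at
`sqrt(lP b)`), which is why the pole-condition calibration is used
throughout.  The default study condition is `N = 240`, `b = 1`, Kuhn length
`10 b`, i.e. `lP = 5 b` (taking Kuhn = 2 lP, the worm-like-chain relation).

### Persistence-length estimation

`persistence_length_estimate` fits `C(s) = <u_n . u_{n+s}> / <|u|^2>` to
`A exp(-s b / lP) + c` over `0 <= s <= N/2`.  Two deliberate choices:

* the additive constant is not optional: ring closure enforces
  `sum_{s=0}^{N-1} C(s) = 0` exactly, which shifts the whole correlation by
  about `-1/N`; dropping it biases the fitted decay length low by ~10% at
  the default conditions.
* raw bond vectors rather than unit tangents are correlated by default.
  For Gaussian (extensible) bonds the unit-tangent correlation has a
  separation-dependent amplitude (rising to `4/pi` at large separation),
  which biases a windowed fit by several percent; the raw bond correlation
  is exactly exponential (plus the closure offset).  `normalize=True`
  restores the unit-tangent variant.

Standard errors come from re-fitting on 20 sample blocks.

## Mode space and dynamics

The transform is the plain DFT `rho_p = (1/N) sum_n exp(-i w_p n) r_n`
(p = 0 is the centre of mass), chosen so that independent bead noises of
variance `2 D` per component map to mode noises with per-component variance
`2D/N` for the purely real modes (p = 0 and p = N/2) and `D/N` for each of
the real/imaginary parts of the rest.  A cosine-only transform would not be
invertible for a general ring; the complex basis with Hermitian symmetry is,
and leaves the per-mode rates unchanged.  Mode noise is drawn by FFT-ing
real-space white noise, which realizes all of these moments (and exact
Hermitian symmetry) with no case analysis.

Each mode relaxes at

    Omega_p = (3/a^2)(1 - cos w_p) + 2 K (1 - cos w_p)^2

and the free dynamics is Euler–Maruyama on the decoupled modes.  One model
subtlety is documented rather than hidden: with the noise normalization
above, the stationary law of this dynamics has mode variances twice the
Boltzmann equipartition values of U (equivalently, it samples U/2).  The
bridge equations, the permutation weights and all conditioned-moment tests
form a self-consistent Ornstein–Uhlenbeck system with rate `Omega_p` and the
stated noise, which is what this package implements; equilibrium *sampling*
(`sample_gaussian_equilibrium`) draws from the Boltzmann distribution of U
by equipartition, independent of the dynamics.

## Bridge conditioning

Conditioning a trajectory to end at `rho^f` at time `tf` adds an exact drift
per mode.  With `tau = tf - t`, `x = Omega_p tau`:

    p = 0:   (rho_0^f - rho_0) / tau                       (Brownian bridge)
    p != 0:  Omega_p [ rho_p^f csch(x) - rho_p coth(x) ]   (OU bridge)

The hyperbolic gains are evaluated via `expm1`-based forms
(`csch x = 2 e^{-x} / (1 - e^{-2x})`, `coth x = (1 + e^{-2x})/(1 - e^{-2x})`),
stable over the ~10 decades of `Omega_p tau` that occur in a run; the
`Omega -> 0` limit reduces continuously to the Brownian-bridge drift.

The conditional drift is singular as `t -> tf`; the integrator's final step
sets the last frame exactly to the target (an `O(dt)` endpoint
regularization, standard for bridge processes).

### Circular-permutation conditioning

For ring-to-ring transitions the bead correspondence is arbitrary up to a
cyclic shift, so the final state is replaced by the set of its N cyclic
relabellings with log-weights

    log P1(n0) = -(N/D) sum_{p>=1} Omega_p |rho_p(n0) - rho_p e^{-x}|^2 / (1 - e^{-2x})

normalized by log-sum-exp (weights remain finite even when all exponents are
hundreds of units below the maximum).  A shift by `n0` only multiplies mode
`p` by `exp(i w_p n0)`, so the full weight vector and the weighted mean
target are circular correlations, evaluated per step with two FFTs
(`O(N log N)`); the generic-target stepper (`step_bridge_permuted`) computes
the same quantities by direct reduction and is tested to agree to machine
precision.  With a single target the permuted stepper collapses bit-for-bit
onto the plain bridge.  At the final step the run lands on the shift with
the largest weight at the penultimate step.  Only the N cyclic shifts are
considered (no reflections or orientation reversals).

Time reversal: a bridge run with swapped endpoints is itself a valid bridge;
the tests check endpoint pinning in both directions.

## Topology analysis

* **Diagrams.** A projection along a random unit vector is scanned for all
  segment-pair crossings (`O(N^2)` exact 2D intersection tests); over/under
  comes from depth, the crossing sign from the right-hand rule.  Non-generic
  directions (grazing endpoints, overlapping collinear images, ambiguous
  depth) raise and trigger a fresh direction; collinear projected segments
  with disjoint extents (ubiquitous after subdividing straight polygon
  edges) are correctly treated as non-crossing.
* **Alexander determinants.**  One Wirtinger relation per crossing gives the
  Alexander matrix; a principal minor's determinant is `±t^m Delta(t)`.
  `|Delta(-1)|` and `|Delta(-2)|` are computed with exact integer
  (fraction-free Bareiss) arithmetic.  The unit `t^m` contributes `2^m` at
  `t = -2`; `m` is recovered exactly as the valuation of the same minor
  evaluated at the prime `2^61 - 1` (far larger than any Alexander
  coefficient of the knots concerned).  The pair `(|Delta(-1)|, |Delta(-2)|)`
  separates all prime knots through 7 crossings — `|Delta(-1)|` alone cannot
  (e.g. 4_1 vs 5_1) — and the table's injectivity is asserted at import.
  Composite knots whose determinant pair escapes the table (e.g. the granny
  knot's (9, 49)) are reported as `unresolved` with the raw values, never as
  an exception.  Diagrams with <= 2 crossings are unknots.
* **Robustness.** `knot_type` first applies a topology-preserving geometric
  reduction (iterative removal of vertices whose triangle no other segment
  pierces, with conservative inclusion tests and an exact coplanar branch),
  then repeats projections until two agree on the determinant pair.
* **Chirality** is the sign of the exact Gauss writhe (|Wr| > 0.5 to call a
  hand; right-handed = positive), since Alexander determinants are
  mirror-blind.  4_1 and 6_3 are reported achiral.
* **Writhe / ACN.**  For one segment pair, every projection direction in
  which the pair crosses yields the same sign, and the crossing probability
  over directions is the pair's mutual solid angle.  Writhe and average
  crossing number therefore have exact polygon expressions
  (`Wr = sum_{i<j} G_ij`, `ACN = sum |G_ij|`), which the reports use by
  default; the uniformly-random-projection estimators (the defining
  construction, 1000 directions in the headline experiments) are implemented
  and tested to agree within Monte Carlo error.

## Endpoint sampling

Parametric initializers give clean polygons of prescribed type: torus curves
for 0_1/3_1/5_1, the standard figure-eight curve for 4_1, and the trace
closure of the braid word `s1^3 s2 s1^-1 s2` for 5_2 (built by an explicit
braid-closure polygon constructor); either chirality by mirroring, verified
by the topology layer on construction.

`mc_equilibrate` turns these into equilibrated self-avoiding conformations:
Metropolis Monte Carlo with crankshaft moves (rotation of a random sub-arc
about the chord through its ends), cylinder-overlap rejection at diameter
`sigma` (default `b/4`), and a move-amplitude cap that bounds every bead
displacement by `sigma` per move.  The cap is what actually protects
topology: overlap rejection alone cannot prevent a finite rotation from
jumping one strand through another, while a passage between two overlap-free
states requires at least `2 sigma` of travel.  The cap depends only on the
arc beads' distances from the rotation axis, which the rotation preserves,
so proposals stay symmetric and detailed balance holds.  Crankshafts change
no bond length and only the two hinge bending terms, so the Metropolis
ratio uses the local energy difference (tested to equal the full one).  The
output's knot type is re-verified.  No claim of full ergodic equilibration
is made for the sweep counts used in tests; endpoints there are
"equilibrated" in the sense of having lost the parametric initializer's
symmetry (documented problem sizes below).

`sample_gaussian_equilibrium` draws exact Boltzmann samples of the phantom
(non-self-avoiding) model by scaling FFT'd white noise to the equipartition
mode variances `<|rho_p|^2> = 1/(2 N Omega_p)` per component; it underpins
the calibration tests.

## Pathway reports and ensembles

`build_report` evaluates, on a stride of stored frames (exact first and last
always included): absolute-frame RMSD to both endpoints (the bridge pins
absolute coordinates, so no superposition by default; superposed RMSD is
available), knot label with determinants, writhe and ACN.  Knot bands are
maximal constant-label runs, with boundaries at midpoints between evaluated
frames, partitioning `[0, tf]`; band boundaries are thus resolved to the
evaluation stride, and no smoothing is applied.  `ensemble_experiment` runs
independently seeded bridges (seeds spawned from one `SeedSequence`) and
reduces them to visiting fractions per label, fractions of trajectories
whose most complex resolved knot has >= k crossings, and dwell-time
distributions.  Labels that remain `unresolved` are reported separately and
never counted towards the >= k-crossing fractions.

## Default numerical parameters

| quantity | default | note |
| --- | --- | --- |
| N | 240 | beads/cylinders per ring |
| b | 1 | length unit; RMS bond length |
| Kuhn length | 10 b | lP = 5 b |
| sigma | b/4 | cylinder diameter (sampling only; off during bridges) |
| D | 1 | bead diffusion; time unit b^2/D |
| dt | 1e-4 | Euler–Maruyama step |
| tf | 2 | bridge duration (20 000 steps) |
| frame stride | 100 | stored frames per run |
| projections | 1000 | when projection estimators are requested |

## Problem sizes used in the test suite

Stochastic checks run at sizes chosen for a CPU-minute budget: conditioned
moment tests use 1000-4000 scalar replicates; calibration recovery uses 2000
equilibrium rings at N = 240; pathway-statistics checks run 8 bridge
trajectories between 0_1 and 4_1 endpoints and 40 between same-topology
5-crossing endpoints (N = 240, dt = 1e-4, tf = 2), with endpoint preparation
of 100 Monte Carlo sweeps from parametric seeds.  At these ensemble sizes the
checks are occurrence checks (each qualitative event observed at least
once), sized for >= 90% binomial detection power at the expected
per-trajectory rates, not rate estimates.

## Known limitations

* The bridge dynamics is phantom by design (excluded volume off), so
  topology changes freely along the path; that is the object of study, not a
  defect.
* The factor-of-two mismatch between the free dynamics' stationary law and
  the Boltzmann distribution of U (above) means long free runs should not be
  used as equilibrium samplers; use `sample_gaussian_equilibrium`.
* Knot calls beyond 7 crossings return `unresolved`; composite knots are
  resolved only if their determinant pair happens to collide with a table
  entry (none through 7 crossings does).
* The Monte Carlo sampler's amplitude cap makes decorrelation slow for large
  sigma-to-size ratios; it is an endpoint generator, not a production
  equilibrium engine.
* Euler–Maruyama endpoint regularization introduces an O(dt) bias in the
  last step; all endpoint checks are exact by construction, interior moments
  carry the usual O(dt) weak error.
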