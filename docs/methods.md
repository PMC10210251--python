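# Methods

## Model and procedure

`tamdkit` treats free-energy reconstruction over collective variables
(CVs) as a three-stage pipeline: (i) sample an extended system in which
auxiliary variables z, tethered to the CVs θ(x), move at an artificial
temperature; (ii) fit the free-energy surface (FES) gradient to the
tethering-force samples in a finite-element basis; (iii) analyze the
resulting surface (minimum free energy paths, basin geometry) and the
underlying trajectories (occupancy, histograms).

**Extended dynamics.** The physical coordinates x follow underdamped
Langevin dynamics at temperature T under
V(x) + Σ_j (κ/2)(θ_j(x) − z_j)², integrated with the BAOAB splitting
(half kick, half drift, exact Ornstein–Uhlenbeck velocity refresh, half
drift, half kick). BAOAB is exact for the harmonic thermostat limit,
which the equipartition and Boltzmann-marginal tests exploit, and reduces
to velocity Verlet at zero friction. Each auxiliary z_j follows
overdamped dynamics γ̄ ż_j = κ(θ_j − z_j) + √(2γ̄/β̄) η_j, discretized
by Euler–Maruyama with the shared timestep; in the operating regime
κΔt/γ̄ ≈ 4·10⁻³ the first-order scheme's bias is far below sampling
noise. Gaussian deviates are generated by an explicit Box–Muller pair
from the uniform stream so that a given seed fully determines the
trajectory bit-for-bit.

The method rests on two assumptions, both checked by tests: *tracking*
(κ large enough that z follows θ; mean |z − θ| shrinks monotonically
with κ) and *adiabatic separation* (γ̄ large enough that z is slow
relative to the conditional relaxation of x; then the spring-force
average at fixed z estimates −∇G(z) at the physical temperature even
though z itself moves at 1/β̄).

**OTFP.** The FES is expanded in chapeau (piecewise-linear hat) bases on
a regular grid; in 2D each cell is split along its lower-left diagonal
into two linear triangular elements, so basis gradients are constant per
element and the normal-equation assembly
A_mn = ⟨∇φ_m·∇φ_n⟩, b_m = −⟨∇φ_m·f_t⟩ is exact without quadrature.
The sign convention is pinned by the requirement that the conditional
mean of f_t = κ(θ − z) at fixed z estimates −∇G(z). Because only
gradients enter, A has one null vector (the constant) per connected
sampled component; the solver pins one node per component, solves the
sparse system, and min-shifts the result. Nodes whose basis support saw
fewer than `min_support = 10` samples stay undefined — a stability
guard against wild values in barely-visited corners; it is configurable
and recorded in the surface provenance. Replica surfaces are averaged
pointwise over the **intersection** of their defined regions (an average
requires a value from every replica) and re-min-shifted.

**Surface lookup and the string method.** Values are interpolated
(bi)linearly from node values. Gradients are central finite differences
of the interpolant at the query point with a half-spacing stencil
(one-sided at the grid edge). Differencing *through the interpolant*
rather than interpolating node-wise differences keeps the stencil
centered on the query; on the benchmark surface this halves the
systematic displacement of the relaxed string near the saddle, which is
what the one-grid-spacing acceptance check measures. The string is
relaxed by steepest descent (step `step_size`, default 10⁻³ Å²·mol/kcal)
alternated with piecewise-linear reparametrization to equal arclength,
until the mean per-point Euclidean displacement between consecutive
parametrized strings falls below `tol` (default 10⁻⁷ Å). Two guards
stabilize the iteration: a move larger than one grid cell halves the
step and retries, and five consecutive increases of the summed path
energy halve it as well; after a successful iteration the step regrows
by 5% toward its nominal value, since a collapsed step would make the
displacement metric small without the string being anywhere near a fixed
point. Endpoints evolve freely and slide into the basin minima.

**Comparing surfaces.** Free energies are defined up to an additive
constant. `fes_rms_deviation` fixes the gauge by least squares (mean
alignment over the common defined region) before taking the RMS, so the
reported deviation is not hostage to the statistical error of whichever
single node happens to be the minimum.

**Finite-tether reference.** A harmonic tether of stiffness κ samples
the marginal of the auxiliary variable, whose Boltzmann factor is the
CV Boltzmann factor convolved with a Gaussian of variance 1/(βκ); for a
quadratic basin of curvature k this is exactly the softened curvature
kκ/(k+κ). `MarginalFEOracle.with_spring_tether` computes this reference
by dense quadrature of the convolution on a spline-refined axis (a
truncated smoothing filter would miss the shifted integrand peak where
the surface is much stiffer than the tether). The harmonic recovery test
compares against this effective curvature; for the soft toy-filter
landscapes the blur (σ ≈ 0.02 Å at κ = 1500) is negligible.

## Parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| physical temperature | 310 | K | physiological thermostat setting |
| thermostat friction | 1 | ps⁻¹ | standard Langevin damping for these systems |
| timestep | 0.002 | ps | the 2 fs step of standard-mass MD |
| spring κ | 1500 | kcal/mol/Å² | reference tethering stiffness; tracking error √(k_BT/κ) ≈ 0.02 Å |
| auxiliary friction γ̄ | 800 | (kcal/mol)·ps/Å² | makes z slow relative to x (time-scale separation ≳ 10²) |
| auxiliary temperature T̄ | 6000 | K | k_BT̄ ≈ 11.9 kcal/mol flattens barriers of 2–10 kcal/mol |
| confinement walls | 300 at z∈{4, 17} | kcal/mol/Å², Å | keep the CV-defining ions inside the filter span |
| wide walls | 100 at z∈{−2, 25} | kcal/mol/Å², Å | two-ion confinement over the extended range |
| exclusion bias k | 600 | kcal/mol | plateau height ≈ 970 k_BT: a prohibitive barrier |
| exclusion ramp width | 1 | Å | C¹ smoothstep ramp; forces continuous at the box faces |
| grid spacing | 0.25 | Å | resolves well widths (σ = 1 Å) with well-conditioned assembly |
| default 1D grid | [3, 18] | Å | filter span: wall bounds with 1 Å margin |
| `min_support` | 10 | samples | defined-node guard (see above) |
| particle masses | 22.99 (ion), 14.01 (gate) | amu | sodium; nitrogen-like gate tip |
| Boltzmann constant | 0.0019872041 | kcal/(mol·K) | fixes the unit system |

Wall stiffnesses quoted in kcal/mol are interpreted as kcal/mol/Å² — the
dimensionally consistent reading of a quadratic one-sided penalty.

## The synthetic stage

`model_systems` provides the study conditions: a harmonic well (exact
closed forms for every stage), a quartic double well
V = h((x/a)² − 1)² + (k_y/2)y² with h = 6 kcal/mol and a = 2 Å (a
~10 k_BT barrier at 310 K, i.e. genuinely rare-event at the physical
temperature, trivially crossed at T̄ = 6000 K), the standard
four-Gaussian 2D benchmark surface with its published constants (three
minima, two saddles — the conventional proving ground for path-finding
methods), and a **toy filter**: one or two ions in a soft cylinder
(radius 3 Å default) with Gaussian binding wells (default centers 5 and
12 Å, depth 3 kcal/mol, width 1 Å) along z, axial Gaussian repulsion
between ions, and a one-dimensional "gate" particle with a double-well
coordinate (±1 Å, 2 kcal/mol) standing in for a charged side-chain tip.
The gate couples to the mean ion z through a saturated (tanh) bilinear
term so that the coupling biases *which* basin combinations are
metastable without dominating the landscape far from the wells; with the
coupling at zero the joint (ion-z, gate) free energy factorizes exactly,
which the tests verify. The default z domain is [−2, 22] Å, matching the
extended histogram range; an `axial` variant restricts ions to z so that
two-ion center-of-mass marginals stay within reach of the quadrature
oracle (≤ 3 non-CV coordinates).

The quadrature oracle computes
G(z) = −(1/β) ln ∫ e^(−βU) δ(θ(x) − z) dx by deterministic trapezoid
quadrature — fixing coordinate-aligned CVs directly, or parametrizing
the null space of a general linear CV with the coordinate-bounds box
projected onto the null basis — and verifies itself by doubling the
resolution (flagged unconverged if the profile moves by ≥ 10⁻³
kcal/mol). Dense-grid search (local minima with plateau deduplication)
and union-find flooding (the minimax/bottleneck saddle between two
basins) provide the independent references for the string method.

What the toys deliberately do **not** emulate: explicit solvent and
membrane, electrostatics and polarization, protein flexibility beyond
one gate coordinate, multi-ion knock-on kinetics, or any force-field
realism. Passing tests therefore demonstrate that the estimators and
path methods are correct and statistically calibrated — not that any
particular channel's free-energy landscape is right.

## Study conditions for the validation runs

- Harmonic recovery: k = 2 kcal/mol/Å², T̄ = 2000 K, 10⁶ force samples
  thinned (every 16th step) from 1.6·10⁷ steps so the slow auxiliary
  (relaxation γ̄/k_eff ≈ 400 ps) decorrelates across the window |x| ≤ 3 Å.
- Double well: T̄ = 6000 K, 10⁶ samples from 1.6·10⁷ steps; barrier and
  minima read off the 0.25 Å grid.
- 2D toy filter: the recovery experiment uses the filter's intrinsic
  confinement with the z domain set to the analysis grid [3, 18] Å and a
  gate grid of ±1.5 Å (covering both gate states and their barrier), so
  every grid node is genuinely sampled and the plain quadrature oracle is
  the exact reference. Three replicas of 2·10⁶ samples, each thinned
  (every 160th step) from 3.2·10⁸ steps. Two estimator choices keep the
  surface error small at a fixed sample budget, neither of which touches
  the free energy being measured: the tether is softened to κ = 250
  kcal/mol/Å² (tracking blur √(k_BT/κ) ≈ 0.05 Å, far below the 0.25 Å
  grid and the 1 Å well width, while the per-sample force noise √(κk_BT)
  drops six-fold from the stiff-tether value — the classic OTFP trade-off
  of tracking fidelity against force noise at a given grid resolution),
  and the physical thermostat is overdamped (γ = 10 ps⁻¹), which
  tightens the adiabatic separation (equilibrium averages are
  friction-independent). The dominant residual error is a smooth
  long-wavelength tilt of the z profile, ~0.15 kcal/mol RMS at these
  conditions.
- String method: benchmark surface gridded at 0.05 units, 57-point
  string, tol 10⁻⁷; references from a 1000×1000 grid search and flood.
- Restraint and occupancy suites: 10⁶-step Langevin runs at 310 K; a
  10⁴-frame programmed-occupancy trajectory (60/40 single/double);
  histogram modes from two pooled 2·10⁶-step runs, one per well.

## Degenerate inputs and edge behavior

Zero excluded particles make the exclusion bias a no-op. Samples outside
the OTFP grid are discarded and counted. Lookups in undefined regions
raise (`OutOfDomainError`); a string point entering one aborts the
relaxation with the iteration logged. An auxiliary wandering more than
10× the potential's domain extent from its CV, or a total energy above
10⁸ kcal/mol, aborts the integrator with a diagnostic. Occupancy counts
above the table's top bin are pooled into it (logged); an occupancy
condition matching no frames yields an empty histogram with a warning.
Structure addressing resolves the first model with alternate locations
taken at highest occupancy, requires unique (chain, residue, atom name)
matches, defaults to the longest protein chain, and names the missing
atom when resolution fails.

## Known limitations

- The auxiliary marginal is Boltzmann at 1/β̄ only in the adiabatic
  limit; at finite γ̄ the sampled z distribution carries O(τ_z/τ_x)
  corrections (measurably so below γ̄ ≈ 20 (kcal/mol)·ps/Å² on the
  harmonic system), though the *reconstructed* FES is unaffected because
  it derives from conditional force averages.
- Near very stiff features (the 300 kcal/mol/Å² walls) the reconstructed
  surface is the finite-tether-softened one (curvature kκ/(k+κ)); use
  `with_spring_tether` on the oracle when comparing there.
- Bilinear interpolation biases saddle heights by up to
  (h²/8)·(|f_xx| + 2|f_xy| + |f_yy|) per cell; the string tests bound
  their profile comparison by exactly this quantity.
- 1D and 2D grids only; no adaptive refinement, no kernel or histogram
  FES estimators, no finite-temperature string variant.
- The trajectory format is the package's own delimited text; external
  MD engine formats are out of scope.
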