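# Methods

This note documents the models and numerical choices behind `elastinv`:
what is computed, under which assumptions, and where the design was
genuinely open.

## Constitutive model and substitution parameters

The material is isotropic linear elastic.  In Voigt ordering
(xx, yy, zz, yz, xz, xy; engineering shear strains) the stress–strain
matrix is `D = E/((1+v)(1−2v)) · (G + vH)`.  `G` and `H` are derived by
matching this bracket to the classical isotropic matrix entry by entry,
which fixes them uniquely: `G = diag(1,1,1,½,½,½)`; `H` has −1 on all six
diagonal entries and +1 on the off-diagonal entries of the upper-left 3×3
block.  A property test verifies the match to 1e−12 relative over random
`(E, v)`.

The substitution modulus `α = E/((1+v)(1−2v))` (Pa) makes `D = αG + αvH`
bilinear in `(α, v)`.  `v = 0` is admitted (no lateral contraction, `D`
still positive definite); `v = 0.5` is the incompressible singularity and
stays strictly excluded.  Valid ranges: `E, α > 0`, `0 ≤ v < 0.5` for
conversions, `0 < v < 0.5` for estimated fields.

## Mesh

The surface marker grid (`n_rows × n_cols`) is extruded through the block
depth into `n_layers` node layers (SI units; bottom layer fixed).  Each
hexahedral cell splits into five tetrahedra — four corner tetrahedra of
volume h³/6 and one central of h³/3 on a cube — with the split parity
alternating in a 3D checkerboard so shared faces use the same diagonal
(conforming mesh; checked exhaustively on a 3×3×2-cell lattice).  All five
tetrahedra of a cell share that cell's `(α, v)`.

The through-thickness discretization is not fixed by the measurement
protocol (only the surface is tracked); it is a config knob.  The
full-scale preset uses `n_layers = 2` — the coarsest volumetric extrusion —
keeping the full 23×13 surface resolution while the whole estimation runs
in seconds; tests use 3 layers on reduced grids.

Linear-tetrahedron geometry: volume `Ve = |det T|/6` with `T` the edge
matrix, strain–displacement matrix `Be` from the barycentric shape-function
gradients (rows of `inv(T)ᵀ`).  `Be` annihilates rigid translations and
maps `u = (x, 0, 0)` to unit axial strain; both are tested, the latter
because an earlier transposition bug passed all energy-based self-checks
while producing physically wrong strains.

## Forward model

Per tetrahedron the operators `A_G = Ve·BeᵀG Be` and `A_H = Ve·BeᵀH Be`
are precomputed once; `Ke = α·A_G + αv·A_H` and the global sparse `K` are
then weighted sums over a fixed sparsity pattern, as are the derivative
actions `(∂K/∂α_j)u` and `(∂K/∂v_j)u` needed by the Jacobian.  One printed
form of the element stiffness omits `α` in the shear-coupling term; the
algebraically consistent form (both terms carry `α`) is used — anything
else contradicts `D = αG + αvH`.

Constraints are applied by eliminating fixed DOFs (row/column deletion),
keeping the reduced `K` symmetric positive definite; static solves use a
sparse LU factorization and fail loudly if the relative residual exceeds
1e−10.

## Linear initialization

For a homogeneous material `K(E, v) = E·K̄(v)` with
`K̄(v) = φ(v)·K_G + ψ(v)·K_H`, `φ(v) = 1/((1+v)(1−2v))`, `ψ = vφ`.  The
initializer minimizes `Σᵢ‖E·Nᵢ(v) − f̃ᵢ‖²` where `Nᵢ(v) = K̄(v)·uᵢ` is the
force response at unit modulus acting on the measured displacement field —
the unique reading that keeps the objective linear in `E`.  The inner
minimizer is closed-form (`E = Σ⟨Nᵢ, f̃ᵢ⟩/Σ‖Nᵢ‖²`); the outer 1-D profile
over `v ∈ (0.01, 0.49)` is scanned on a 49-point grid and refined by a
bounded golden-section pass to 1e−4 (the profile need not be convex; on
strongly mis-specified data its minimum can sit at the search bound).
Both per-deformation-set fits and a pooled fit are provided; the pooled
fit initializes and anchors the nonlinear stage.

## Nonlinear inverse problem

The estimate minimizes

    Σᵢ ‖K(α,v)·uᵢ − f̃ᵢ‖²  +  γ·s²·Σⱼ [((αⱼ−α̂₀)/α̂₀)² + ((vⱼ−v̂₀)/0.5)²]

over packed coordinates `x = [log α, logit 2v]`, so the published
unconstrained solver runs unchanged while feasibility is guaranteed.
Scaling choices:

- `s² = Σᵢ‖f̃ᵢ‖²/(2k)` makes the anchor rows commensurate with the force
  residual, so γ is a unitless relative weight.
- α deviations are scaled by the anchor `α̂₀` (no natural scale exists);
  v deviations by the fixed width 0.5 of the admissible range.  Scaling v
  by the fitted `v̂₀` was tried first and rejected: when the homogeneous
  fit lands near its search bound (`v̂₀ ≈ 0.01` on heterogeneous data) the
  anchor term inflates ~2500× and biases every vⱼ toward the bound.
- γ defaults: `1e−6` for noiseless studies (anchor influence negligible,
  pure recovery), `3` for the noisy surface-only protocol — strong enough
  that the anchor counterbalances the noise-induced force-residual
  gradient at 1 mm marker precision, weak enough that heterogeneity still
  moves the estimate; held-out error is flat for γ anywhere in [3, 300].

The residual stacks, per load case, the free-DOF force residual, followed
by the scaled anchor rows; `‖Y‖²` equals the objective exactly (tested
against an independent scalar evaluation).  The analytic Jacobian chains
the per-hexahedron stiffness derivatives through the bound transform and
is verified against central finite differences.

**Surface-only measurements.**  The residual needs full displacement
fields but only surface markers are tracked.  Unmeasured DOFs (interior
nodes and held-out surface markers) are completed by static condensation:
they are solved from equilibrium at a homogeneous material with the
pooled-fit Poisson ratio, holding measured markers at their recorded
values.  Young's modulus cancels because unmeasured DOFs carry no external
force; the loaded marker must be measured.  The completion runs once,
before the nonlinear solve (first provisionally at v = 0.25 to run the
linear fit, then at the fitted `v̂₀`), so the completed field is fixed
data and the Jacobian stays consistent.  Synthetic studies can bypass
completion and supply the exact full field (`use_full_field`).

## Self-adapting Levenberg–Marquardt

Step: `d = −(JᵀJ + λI)⁻¹JᵀY` (dense Cholesky).  Damping:
`λ = η·[θ·m/‖Y‖ + (1−θ)·m/‖JᵀY‖]`, `m = min(‖Y‖², ‖JᵀY‖²)`, with `η`
multiplying the whole bracket, the only reading under which η is a single
global adaptive factor.  The mixture's units are inconsistent across the
two terms; it is implemented exactly as published, not rescaled.  Gain
ratio `τ` = actual/predicted squared-residual decrease; acceptance is
strict (`τ > p0`); `η` updates every iteration, accepted or not, via
`η ← min(c, η·q(τ))`, `q(τ) = max(0.5, 1−(2τ−1)²)`.

Because `q ≤ 1`, η — and with it λ — can only shrink; after a rejected
step the scheme would re-propose an ever less damped step and stall in a
permanent rejection loop (observed on the standard banana-valley test
problem).  The solver therefore adds a rejection safeguard: a multiplier
ν on λ that quadruples while steps are rejected and resets to 1 on every
acceptance.  On any accepted path the published update is exactly what
runs; the safeguard only engages to escape stagnation.  With it the solver
passes the standard checks (affine residuals → normal-equations solution,
τ ≡ 1; banana valley from (−1.2, 1) → (1, 1)).

Defaults (the method prescribes none): ε = 1e−8, θ = 0.5, c = 1e4,
p0 = 1e−3, η₁ = 2c, max_iter = 500.  Ties τ = p0 reject.  A predicted
decrease that underflows to ≤ 0 is treated as a degenerate, rejected step.
The solver is deterministic and traces every iteration.

## Force correction ensemble

Base regressors (pluggable; stock: cubic polynomial ridge, RBF ε-SVR, RBF
kernel ridge as the least-squares kernel machine) fit voltage → force on
min–max normalized data.  Weights `ω_i = (1/E_i)/Σ(1/E_k)` with `E_i` the
summed relative training error; a perfect base model takes all weight
(with a warning).  The combiner fits the weight-scaled prediction vector
to the reference force.  Its stock choice is a **linear-kernel** SVR: the
second stage is a re-weighting of base predictions, i.e. linear by
construction, and an RBF combiner measurably hurt held-out MAE on
synthetic calibration data.  A plain weighted-sum combiner (`"sum"`) is
also provided and makes a one-model ensemble reproduce that model exactly.
Gram→Newton conversion uses g = 9.8 m/s².  Error metrics are the plain
mean absolute error, mean of squared errors, and mean absolute percentage
error (percent; undefined and rejected when any reference force is zero).

## Synthetic data generator

The generator defines the study conditions; its defaults are the
reference setup: 23×13 markers on a 50×30×10 cm block, bottom fixed, load
at row 7 / column 12, six force magnitudes 18.5814–30.1766 N (the
corrected forces of the six reference deformation sets), displacement
noise 1 mm (tracker precision), calibration forces 2–3000 g with an
affine five-channel response, a cubic drift (15% of full-scale gain) and
5 mV channel noise.  Parameter fields are drawn in `(E, v)` — defaults
E ∈ [6, 9] kPa, v ∈ [0.05, 0.10], matching the magnitudes the linear fits
report for soft foam — as sums of ≤3 low-frequency cosine modes per axis,
mapped into range and contracted toward the midrange until adjacent cells
differ by < 20%, the local-similarity structure the estimator assumes.
All draws are seeded; ground truth and noiseless copies are retained.

What the generator does **not** emulate: genuine material nonlinearity
(every load case comes from the same linear system, so the six magnitudes
probe proportional fields), indenter contact geometry (the load is a
single nodal force), viscoelastic slow-rebound memory, and marker-volume
bias.  Passing tests therefore demonstrate correctness of the estimation
machinery and its noise behavior, not fidelity to any physical pillow.

## Evaluation protocol

Markers split 249/50 (seeded uniform; the loaded marker is forced into
the sample set, since the applied force must act at a measured node).
Per-deformation-set linear fits and the pooled nonlinear estimate are each
pushed through the forward model under the known loads; predicted and
measured displacements are compared at the held-out markers as per-node
Euclidean norms, reported as dmax/dmean in millimeters (SI internally, mm
only at the reporting boundary).  The protocol is deterministic given
config and seed, and the LM estimate never worsens the data objective of
its initializer.

Problem sizes: oracle and solver tests run on 2–30-hexahedron meshes;
recovery studies use a 6×4×3-node mesh (30 hexahedra, 60 parameters); the
noisy protocol runs the full 23×13×2 preset (264 hexahedra, 528
parameters, 897 free DOFs) over ten seeds.

## Known limitations

- The inverse problem is only locally identifiable: elements far from the
  indenter have weak sensitivity, and with all loads at one marker the
  effective data are one displacement shape per magnitude.  Regularization
  handles this; moving the load between markers would genuinely enrich
  the data.
- The completion step assumes homogeneous equilibrium for unmeasured
  DOFs; on strongly heterogeneous materials it injects model error into
  the "measured" fields.
- Geometric linearity is assumed throughout, although the simulated
  deformations (several cm on a 10 cm block) would be large-strain in
  reality.
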