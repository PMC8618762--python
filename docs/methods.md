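# Methods

## Signal model and dictionary

The diffusion signal of a coherent fiber population is modelled as a
mono-exponential Gaussian response: for a gradient with b-value b (s/mm²)
and unit direction q̂, a fiber along d responds with
exp(−b q̂ᵀ D(d) q̂), where D(d) is the axially symmetric tensor with
longitudinal diffusivity λ1 = 17×10⁻⁴ mm²/s along d and transverse
diffusivities λ2 = λ3 = 3×10⁻⁴ mm²/s.  Two isotropic atoms model gray
matter (λ = 17×10⁻⁴) and CSF (λ = 30×10⁻⁴); their responses depend only on
b, never on q̂.  The b=0 row of the dictionary is set to 1 exactly, so that
fitting the (fully sampled) b=0 data constrains each voxel's coefficients to
sum to one — the volume-fraction normalization enters the inverse problem
through the data rather than as an explicit constraint.

The rotation carrying the reference axis to d is built by the Rodrigues
formula; with λ2 = λ3 the resulting tensor is independent of the residual
in-plane rotation freedom.  b-values are taken directly from the gradient
table and never derived from |q|.

Hemisphere discretization uses a spherical-Fibonacci lattice with latitudes
z = (2i+1)/2n in (0, 1): all points lie in the open upper hemisphere (no
antipodal duplicates), coverage is quasi-uniform, and the construction is
deterministic — a seed only permutes the labelling so that seeded
experiments decorrelate.  Angles between directions are axial throughout,
arccos |d·d′| ∈ [0°, 90°], because FODs are antipodally symmetric.

## Acquisition model

Volumes are flattened in C order with 0-based indexing.  The 3D FFT is
unitary with DC at the grid center; for even grid dimensions the centering
shifts are implemented as checkerboard sign flips (exact, cheaper than array
rolls).  With this convention the adjoint of the FFT equals its inverse, so
on fully sampled data A†A is a per-voxel operator and step-size bounds are
easy to reason about.  Masks act as sample selectors; zero-filling appears
only in adjoints.  The gradient of the data-fit term ‖AZ(S) − Ŷ‖² is kept
with its factor 2.

k-space masks follow a two-phase EPI pattern along the phase-encoding axis
(axis 0): a fully sampled central band — at least 4 lines, default 1/8 of
the lines — plus every skip-th peripheral line, identical on every slice.
The b=0 gradient is always fully sampled (calibration and normalization
depend on it).  A solver maps a target under-sampling factor N/K to
(center width, skip, admissible peripheral offsets): skips are searched from
densest periphery upward, center widths from widest downward, and every
peripheral phase offset that lands within ±10% of the target is recorded;
per-gradient offsets are then drawn (seeded) from that admissible set.  This
keeps the central band identical across gradients while the periphery
varies, and it reaches factors up to 10 on realistic line counts (on very
short axes, e.g. 16 lines at factor 4, the admissible offsets align the
single peripheral line with the center — the degenerate but valid limit of
the two-phase scheme).

## Synthetic phantom and simulator

The phantom fills an ellipsoid with concentric tissue shells (WM core
ρ ≤ 0.55, GM 0.55 < ρ ≤ 0.8, CSF 0.8 < ρ ≤ 1).  White matter hosts two
orthogonal in-plane fiber bands; their overlap holds two-fiber crossings,
and the two central slices of the overlap add a third, through-plane fiber
— a spatially coherent 3-fiber slab rather than isolated voxels, since the
structured-sparsity prior is designed around spatial coherence and a
one-voxel bundle is exactly what it suppresses.  Remaining WM voxels carry
a single fiber.  Volume fractions are 1, (0.5, 0.5), and (0.35, 0.35, 0.30);
every fiber's mass sits on the single nearest dictionary direction so that
peak-level checks against the truth are exact.  GM and CSF voxels carry mass
1 on their isotropic atom.  s0 is a smooth bump normalized to mean 1 over
the brain.

Coil sensitivities are complex Gaussian lobes placed around the volume with
low-order polynomial phases (C = 4 by default); their sum of squares is
strictly positive everywhere.  Phase maps combine a motion surrogate — a
linear phase ramp along the phase-encoding axis whose induced k-space shift
is drawn uniformly within ±10 lines (zero for the b=0 volume) — with a
smooth low-frequency inhomogeneity term of configurable amplitude (default
0.3 rad; the spatial statistics of realistic field inhomogeneity are not
prescribed anywhere, so this is an explicit stand-in).  Noise is complex
i.i.d. Gaussian added in k-space with σ = ⟨s0⟩/SNR per real/imaginary
component (SNR = 30 by default), where ⟨s0⟩ averages over brain voxels only
— including background would dilute the definition.  All randomness flows
through explicit integer seeds; equal seeds give bit-identical outputs.

What the simulator does *not* model: Rician magnitude statistics (noise is
Gaussian in k-space by construction), EPI geometric distortions and eddy
currents, T1/T2 relaxation, partial-volume mixtures (boundary voxels take
their majority tissue), and per-voxel response variability.  Passing tests
therefore demonstrate correctness of the estimator under its own model
assumptions, not robustness to the full physics of scanner data.

## Solver

One weighting cycle solves the constrained least-squares problem by
forward–backward splitting.  The step applied to the factor-2 gradient is
γ_s/(2‖A∘Z‖²) with safety factor γ_s ∈ (0, 2), default 1.9 — equivalently a
step strictly inside (0, 2/‖A‖²) in the half-gradient convention.  The
spectral norm is estimated by power iteration on the Gram operator
(tolerance 1e-6).  Optional Nesterov acceleration (off by default; no
convergence guarantee in the stochastic setting, but it reaches the same
minima much faster in practice) caps the safety factor at 0.99, because the
accelerated iteration requires steps within 1/L rather than 2/L.

The stochastic variant keeps a table of per-coil gradients: each iteration
recomputes the gradients of n_fixed fixed coils (indices 0..n_fixed−1) plus
n_random coils drawn without replacement from the remainder (seeded
generator advanced per iteration), and updates the aggregate by the
difference of new and stored values.  With the subset equal to all coils the
aggregate is re-summed freshly each iteration, making the deterministic path
bit-identical to a textbook projected-gradient loop.  Iterations stop when
‖S(j+1) − S(j)‖ < ν‖S(j)‖ (ν = 10⁻³ by default) or at max_iter; a
diagnostics hook records objectives and aborts if the objective exceeds ten
times its initial value or becomes non-finite.

Projection onto the nonnegative weighted-ℓ1 ball {x ≥ 0, Σ wᵢxᵢ ≤ κ} first
tries the orthant clip; if infeasible it solves for the KKT multiplier μ in
xᵢ = max(0, vᵢ − μwᵢ), Σ wᵢxᵢ = κ by sorting the breakpoints vᵢ/wᵢ
(descending, ties by index) — exact in O(m log m).  Entries with wᵢ = 0 are
outside the ball's reach and only clipped.

## Reweighting

After each cycle the weights are W = 1/(τ + B), where B is a spatio-angular
blur of |S1|: a sum over the 15° angular cone of each direction and an
average over the 26-connected spatial neighborhood of each voxel (clipped at
volume borders, restricted to white-matter voxels; the voxel itself is
included, consistent with each direction belonging to its own cone).  The
normalization is by the spatial neighborhood size only: fiber mass spread
over adjacent dictionary directions should reinforce the blur, not dilute
it.  τ starts at the population variance of B(0) (falling back to the floor
when B(0) is constant) and decays by a factor 10 per cycle down to
τ̄ = 10⁻⁶·max B(0) (the floor is not prescribed anywhere; it is exposed as
`tau_bar_rel`).  Cycles warm-start from the previous solution and stop after
T = 10 cycles or when the relative S1 change drops below 10⁻³.

The ball radius default is κ = 4·N_wm for single-shell data (5·N_wm for
multi-shell).  The weighted norm of the *true* field under converged weights
approaches its support count — between N_wm and 3·N_wm for one to three
fibers per voxel — which is why the radius must exceed N_wm even though unit
weights give ‖S1_true‖₁ = N_wm exactly.  For ground-truthed validation,
`reweighted_solve(kappa_oracle=S1_true)` recomputes κ_t = Σ W(t)|S1_true|
each cycle: the tightest ball that keeps the truth feasible at every stage.
This oracle mode exists only for synthetic experiments where the truth is
known.

## Baselines

TV–L2+ and TV–STR+ first recover complex DW volumes per gradient by
TV-regularized SENSE (Condat–Vũ primal–dual: explicit gradient on the data
term, pointwise dual-ball projection for isotropic TV with forward
differences and Neumann boundaries; step sizes strictly inside the stability
region).  Phase maps are deliberately not modelled — magnitudes are taken
and divided by s0, as two-step pipelines do.  The FOD step is per-voxel
nonnegative least squares (scipy) for TV–L2+, or the same reweighted
structured-sparsity solver in q-space for TV–STR+ — implemented by reusing
the main solver with a trivialized acquisition model (full masks, one unit
coil, zero phase, unit s0), exact because the unitary FFT preserves the
objective.  The one-step TV+ method minimizes
‖A(X) − Ŷ‖² + λ‖ΦX‖_TV over X ≥ 0 by the same primal–dual scheme with a
positivity clip in the primal step.  The published parameter ranges for the
full-scale setting are recorded as module constants; on the desk-scale
phantom (s0 of order 1) the useful λ are of order 10⁻²–10⁻¹ and a
grid-search helper is provided.

## Peak extraction and evaluation

A direction is a peak candidate if its coefficient is positive and is not
exceeded within its 30° cone; candidates below 20% of the voxel maximum are
discarded; greedy selection by amplitude (ties by index) enforces pairwise
cone separation and caps at 8 peaks.  Evaluation matches estimated to true
fibers greedily (smallest axial angle first) within a 30° tolerance: a voxel
succeeds when the counts agree and every pair matches; unmatched estimates
and truths count as false positives and negatives.  The mean angular error
averages, over all true fibers, the angle to the closest estimated fiber
regardless of matching; a voxel with no estimated peaks contributes the
worst case 90° per true fiber (declared convention).  Evaluation is
restricted to the white-matter voxels of the truth.

## Problem sizes and numerical choices

Tests and the reference-quantity script run on desk-scale instances chosen
to exercise every code path with sharp oracles: dictionaries of 4–96
directions, phantoms from 8×8×4 to 16×16×10 voxels, 2–15 diffusion
gradients, 4 coils.  Exact-recovery and trend experiments use the 16×16×10
phantom with n = 48 directions (angular resolution ≈ 13°, comfortably finer
than the 30° evaluation cone).  Solver-equivalence checks use deliberately
overdetermined per-voxel systems (n + 2 < M + 1) so the objective is
strongly convex and both solver variants converge to the same value within
1e-6.  Full-scale reproduction of published whole-brain experiments
(90×90×108 voxels, n = 500, cluster-scale runtimes) is out of scope.

Floating-point comparisons in the ball projection use 1e-12 absolute slack;
power iteration runs to 1e-6 relative; the phase-map k-space shift is
measured by 16× zero-padding and parabolic interpolation of the spectral
peak (≤ 5×10⁻⁵ lines of bias, versus ~0.1 for a plain circular centroid —
material when verifying a 10-line bound).

## Known limitations

Recovery of three-fiber crossings degrades first under noise and
under-sampling (visible as false negatives at SNR 30 with 4-fold k-space
under-sampling); the weighted-ball projection treats the white-matter block
globally, so κ trades off sparsity across all voxels at once; the two-phase
mask model fixes the readout direction as fully sampled and does not cover
non-Cartesian trajectories; and the stochastic solver's convergence with
Nesterov acceleration is empirical, not guaranteed.
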