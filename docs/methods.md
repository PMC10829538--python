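# Methods

This note records the models, conventions and numerical choices behind
`pemlearn`, including decisions that were genuinely open and the reasoning
for the defaults.

## Diabatization model

For each geometry the manifold of n excited states enters as ascending
adiabatic energies **V** plus ground-state transition multipoles (dipole
μ₀ₐ; optionally Cartesian quadrupole Q₀ₐ and octupole O₀ₐ as full raw
tensors, Frobenius products taken over all components including the
symmetric redundancy — no traceless projection). The property matrix at
level tD/tDQ/tDQO uses unit weights ω_Q = ω_O = 1 by default. Its
eigenvector matrix **T** defines U = TᵀVT.

Eigenvector convention: columns ordered by **descending** eigenvalue of P;
each column's largest-magnitude component made positive. This makes a single
run reproducible but deliberately does *not* remove the cross-geometry gauge
arbitrariness — fixing that is the correction step's job, and the synthetic
tests rely on the raw output genuinely exhibiting it. Degenerate property
eigenvalues (relative gap < 1e-8) leave the transformation ill-defined in
the degenerate subspace; the PEM is flagged and a warning emitted rather
than any attempt at subspace rotation.

The ground state is excluded from the manifold; the manifold is a contiguous
user-chosen window of excited states (e.g. states 4–8 of a small molecule).
Energies are eV at the interface; Hartree input is converted on read.

## Molecular representation

Feature vector x_(i,j) = r_ref(i,j)/r(i,j) over canonical (i<j) atom pairs —
dimensionless "normalized inverted distances"; the reference distances are
the ensemble means of each pair distance (computed after permutation
canonicalization; the alternative order was open and we canonicalize first
so that equivalent-atom swaps cannot blur the means). The reference
geometry maps to the all-ones vector. The representation is exactly
invariant under rigid motions and inversion; permutational invariance over
chemically equivalent atoms is enforced by reordering each declared
equivalence group by ascending distance to a reference atom (ties broken by
original index — idempotent and deterministic), and inversion invariance by
reflecting through a declared three-atom plane whenever a test atom sits on
its negative side. Ensemble alignment is Kabsch with proper rotations only
(det = +1); handedness is never changed by alignment.

## Kernel ridge regression

Gaussian kernel k(x,x′) = exp(−‖x−x′‖²/(2σ²)) — the convention the σ grid is
defined on. Closed-form fit α = (K+λI)⁻¹y by Cholesky factorization; the
factorization is cached per (X, σ, λ) and shared by every surface / PEM
element trained on the same geometries, and leave-one-out (LOO) predictions
use the identity y_i − ŷ₋ᵢ = αᵢ/[(K+λI)⁻¹]ᵢᵢ instead of n refits.

Default grids: σ log-spaced over [10⁻², 10²] × median pairwise feature
distance (9 points; the median heuristic is scale-free), λ log-spaced
10⁻¹²…10⁻¹ (12 points). Hyperparameters are selected per target by 10-fold
seeded-shuffle cross-validation; CV ties break toward larger λ, then larger
σ (the smoother model). Assignment solutions are ranked by nested CV
(outer 5-fold / inner 10-fold by default; fold counts were not prescribed)
so tuning never leaks into the ranking score.

Centering: whether targets are centered was an open choice. `fit`/`predict`
mean-center by default (the mean is restored at prediction) so that queries
far from training data revert to the training mean rather than to zero;
`center=False` gives the plain form. The public `loo_predictions` is
uncentered so that it matches the refit-per-point oracle exactly; the EM
loop centers internally (full-sample mean — the O(1/n) leak is irrelevant to
an internal ranking loss) because without it badly-fitted initial clusters
all predict ≈0 and the assignment step carries no signal. Duplicate feature
rows at λ = 0 are detected (distance < 1e-12) and reported by row indices in
the singularity error.

## The EM correction

State: one signed permutation per geometry (signs all +1 in the plain
reordering case). The loss is the mean squared LOO error over all targets —
surfaces in the reordering case, independent PEM elements (upper triangle,
each coupling counted once, since each element has one model) in the
diabatic case. The loss is invariant under one global signed permutation
applied to all geometries; results are compared modulo this gauge, with the
global sign fixed by making the first state's sign +1.

Each sweep: (expectation) refresh hyperparameters by grid CV on the current
clusters; (maximization) visit the geometries in a seeded random order and
reassign each one with that geometry excluded from training — a linear sum
assignment (Jonker–Volgenant; exact lexicographic tie-break by greedy
prefix-fixing with re-solves) on squared prediction errors for energies, and
for PEMs a signed-permutation search: linear assignment on the diagonal
first ("diag-then-signs", couplings neglected), exhaustion of the 2ⁿ⁻¹ sign
vectors, then in `full` mode an exhaustive sweep of all 2ⁿ⁻¹·n! candidates
(guarded at n > 8) or, for larger manifolds, 2-opt hill climbing over
transpositions and single sign flips. Clusters are updated immediately
after each geometry. A sweep with no changes terminates the phase;
revisiting an earlier assignment state (oscillation) also ends it, flagged
as unconverged.

### Hyperparameter refresh schedule (annealing)

Refreshing on the full grids from a cold start systematically freezes into
domain-wall local optima: CV, scoring only the fit of the *current* labels,
happily selects flexible models (small σ and/or tiny λ) that fit spatially
coherent wrong domains, after which no single-geometry move improves. The
refresh therefore follows a deterministic-annealing schedule — each phase
restricts the σ and λ grids to their upper (smoother, more regularized)
fractions and runs sweeps to convergence before the next phase opens the
grids further. The default schedule is (0.99, 0.99) → (0.6, 0.85) →
(0.45, 0.75) → (0.33, 0.67) → (0, 0) as (σ, λ) grid cut-off fractions: the
first phase is a pure mean-field (only the smoothest, most regularized grid
point), which sorts states onto separated surfaces and aligns coupling signs
to the global majority before any spatial flexibility exists to entrench
mistakes. A single all-zero phase recovers plain full-grid refresh.

### Domain repair

Annealing still leaves occasional spatially coherent misassigned domains —
typically a crossing-seam region or a segment between a seam and the
sampling-box edge, where kernel predictions revert to the mean and no
correctly assigned anchor exists beyond. After the schedule, repair passes
run (for ensembles of ≥ 20 geometries): flag the worst-fitted geometries
(top quartile of per-geometry LOO loss, dilated by 4 nearest neighbours,
capped at 65 %), then try three proposal generators in order — (a) predictions
from models retrained on the unflagged geometries only, (b) local
first-order (linear) extrapolation from the 10 nearest unflagged geometries,
which continues trends through seams and past edges instead of reverting to
the mean, and (c) the nearest unflagged neighbour's corrected targets.
Proposals from (b) and (c) are accepted per geometry only when they beat the
current assignment's objective by a factor of 4 (margin gate), protecting
marginal cases from heuristic flips. After each proposal batch the normal
sweeps re-converge; the pass is kept only if the total loss strictly
decreased, otherwise rolled back — so the reported loss never increases
across repair rounds. Up to 6 rounds by default.

### Restarts

The procedure remains stochastic; `multistart_select` runs the EM from the
identity ordering plus seeded random initial orderings (the reordering
study default is 1000 restarts; the diabatic case has no prescribed count
and is configurable), ranks converged solutions by nested CV, and breaks
ties by lower loss, then lower restart seed. Restarts are independent, so
results do not depend on execution order.

## Wavefunction-overlap benchmark

CIS-type states (the form TDA amplitudes take) over spin-adapted singlet
single excitations; the overlap of two states at different geometries is the
CI-weighted double sum over determinant pairs, each pair a product of an
α- and a β-block determinant of occupied-MO cross overlaps S_MO = C₁ᵀS_AO C₂,
with the 1/2 spin-adaptation weight. All occupied orbitals of the expansion
are included (frozen-core treatment was unstated; none is applied). AO
cross-overlap matrices are consumed, never computed — there is no integral
engine in scope; the synthetic module fabricates consistent ones. Distance
d = 1 − |overlap| (phase-insensitive); magnitudes beyond 1 + 1e-8 raise, as
they signal inconsistent inputs. Clustering maximizes the mean silhouette
s(i) = (b−a)/max(a,b) directly (singletons score 0 — the standard
convention), under the constraint that the states of one geometry occupy
distinct clusters: per geometry, provisional silhouettes for every
(state, cluster) placement feed a maximizing linear sum assignment, updated
immediately, swept until stable.

## Wigner sampling

Thermal harmonic Wigner density per mode: independent Gaussians with
Var(q) = coth(ω/(2k_BT))/(2μω) and Var(p) = (μω/2)·coth(ω/(2k_BT)) in
atomic units (ħ = 1); coth → 1 at T = 0 (ground-state Wigner function) and
Var(q) → k_BT/(μω²) in the classical limit. Frequencies are read in cm⁻¹
and converted via constants pinned in `pemlearn.constants` (CODATA-2018).
Zero-frequency modes must be excluded; imaginary frequencies raise.
Momenta are sampled but only geometries feed the regression pipeline.
Cartesian reconstruction: Δx_A = √(μᵢ/m_A)·L_(i,A)·qᵢ with mass-weighted
orthonormal displacement vectors (checked to 1e-6).

## Synthetic ground truth

The generator exists so that every algorithm is testable without
electronic-structure data. A diabatic model holds one smooth element
function (constant + linear + Gaussian bump) per independent PEM element on
the box [−1, 1]^dim. Defaults: diagonal offsets spaced 0.5 eV with
alternating slopes of 0.35 eV per unit coordinate and couplings ≈ 0.1 eV —
neighbouring excited states a few tenths of an eV apart, couplings an order
of magnitude smaller, and crossing seams localized (surfaces swap energetic
order over a minority of the box), the regime a thermal ensemble of a small
molecule exhibits. Presets: `avoided_crossing_1d` (two states, coupling
0.02 eV — a narrowly avoided crossing whose cusp-like transition is narrower
than typical training spacing, the regime where direct adiabatic fitting
degrades and the headline comparison is meaningful); `uncoupled_state_1d` (three
states, one with identically zero couplings, crossing the others exactly —
reordering alone is exact diabatization for it).

`scramble` conjugates each PEM by an independent uniformly random
gauge-fixed signed permutation and records the truth. `synth_multipoles`
assigns each diabatic state a fixed orthogonal multipole direction (axes
for the first three states, orthonormal quadrupole basis tensors beyond)
with distinct magnitudes modulated smoothly (±15 % tanh), rotates them by
the adiabatic eigenvectors, and applies random per-state ±1 phases — so
property-matrix diabatization of the synthetic records reproduces the
realistic raw-output defects, and recovery modulo gauge is exact when the
multipole Gram matrix stays non-degenerate. The toy CIS bundle drifts
orthonormal MO sets along a 1-D path with CI vectors that are rows of
exp(θ(t)·A) for a fixed skew generator (exactly orthonormal, smoothly
mixing, character-preserving) and swaps the stored (energy) order of the two
lowest states mid-path — the defect character clustering must detect.

What the generator does **not** emulate: real electronic-structure noise,
states entering/leaving the manifold, property-matrix degeneracies along
seams, anharmonic sampling, and size-intensive multipole scaling. Passing
tests demonstrate correctness of the algorithms under the stated smooth
ground-truth conditions, not accuracy on any specific molecule.

## Problem sizes and evaluation conventions

The test-suite and acceptance studies use 100-geometry ensembles (30
training points for regression comparisons, the small-data regime the
method targets), three-state manifolds for scramble recovery, and 10⁵
Wigner draws per mode — sizes chosen so each study is decisive at
Monte-Carlo precision. The prediction score is the mean absolute error over
all states and all held-out geometries, in eV; in the diabatic route the
predicted PEMs are diagonalized and the ascending eigenvalues compared with
the true adiabatic energies.

## Known limitations

- The correction repairs gauge defects only; it cannot compensate a
  property set that fails to distinguish the states (degenerate property
  matrix) or a badly chosen manifold.
- Exhaustive per-geometry search is exponential in the state count
  (guarded at n > 8); 2-opt mode is a heuristic with no optimality
  guarantee.
- The repair stage's proposals assume the sampled region is connected;
  disconnected sampling islands have no clean anchors to extrapolate from.
- Nested-CV ranking of restarts shares hyperparameters across targets
  within each inner search; per-target nested searches would be costlier
  with no effect observed on ranking.
- File-based runs of the full `run_pipeline` need a feature source;
  records + geometry ensembles are wired through the library API, while the
  YAML driver currently executes synthetic presets end to end.
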