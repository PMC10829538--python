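# pemlearn

Machine-learning-corrected property-based diabatization of excited-state
potential energy matrices, with kernel ridge regression (KRR) for predicting
adiabatic energies from small training sets.

## The problem

Adiabatic potential energy surfaces (PESs) of electronically excited states
are ordered by energy at every nuclear geometry, so same-symmetry surfaces
never cross — instead they form avoided crossings and conical intersections
where energies and properties are sharply kinked. Those kinks ruin
regression: a kernel model needs dense training data exactly where *ab
initio* calculations are most delicate. In a diabatic representation the
potential energy matrix (PEM) **U**(**R**) = **T**(**R**)ᵀ**V**(**R**)**T**(**R**)
is smooth — diabatic states may cross — and the adiabatic energies are
recovered at any geometry by diagonalizing the predicted PEM.

Property-based diabatization builds **T** cheaply from ground-state
transition multipoles: the property matrix

    P_ab = μ₀ₐ·μ₀ᵦ  [+ ω_Q ⟨Q₀ₐ, Q₀ᵦ⟩_F]  [+ ω_O ⟨O₀ₐ, O₀ᵦ⟩_F]     (tD / tDQ / tDQO)

is diagonalized per geometry and its eigenvector matrix used as **T**. But
the raw output is gauge-scrambled: each geometry's diabatic states come out
in an arbitrary order, and the couplings carry random signs inherited from
the electronic wavefunction phases — both elements of the signed-permutation
group (2ⁿ⁻¹·n! elements for n states, after fixing the irrelevant global
sign).

`pemlearn` repairs both defects with an expectation–maximization (EM)
procedure that couples clustering with KRR: fix the per-geometry
assignments, train one Gaussian-kernel ridge model per PEM element (grid
cross-validated hyperparameters, closed-form solution α = (K+λI)⁻¹y via
cached Cholesky factorizations); then sweep the geometries, reassigning each
one to the signed permutation S minimizing ‖A − SᵀUS‖_F against the PEM A
predicted by models trained without that geometry (closed-form leave-one-out).
Competing solutions from random restarts are ranked by nested
cross-validation. The same machinery reorders plain adiabatic energies into
smoother crossing surfaces (no diabatization needed for states of different
symmetry), and a wavefunction-overlap route — CIS determinant overlaps,
d = 1 − |⟨Ψᵢ|Ψⱼ′⟩|, silhouette-maximization clustering — provides an
independent benchmark. A thermal harmonic Wigner sampler generates the
nuclear ensembles.

Who it is for: quantum-chemistry practitioners who have TDDFT/TDA-level
excitation energies and ground-state transition multipoles for a sampled
ensemble and want global excited-state surfaces from dozens–hundreds of
training points instead of thousands.

## Worked example

Generate a two-state model with a narrowly avoided crossing, scrambled by
per-geometry diabatization gauges, correct it, and compare held-out
prediction accuracy of the two routes:

```python
import numpy as np
from pemlearn import synthetic, pipeline
from pemlearn.assignment import OptimizationConfig

model = synthetic.avoided_crossing_1d(seed=1)
coords = synthetic.sample_coords(1, 100, seed=11)
records, _ = synthetic.synth_multipoles(
    model, coords, synthetic.MultipoleSpec(include_quadrupoles=False), seed=21
)
train, test = pipeline.train_test_split(100, 30, seed=31)
out = pipeline.compare_bases(
    coords, records, train, test, level="tD",
    config=OptimizationConfig(n_restarts=1, seed=41, mode="full"),
)
print(f"adiabatic-basis MAE : {out['mae_adiabatic_ev']:.2e} eV")
print(f"diabatic-basis  MAE : {out['mae_diabatic_ev']:.2e} eV")
print(f"ratio               : {out['mae_ratio_diabatic_over_adiabatic']:.4f}")
```

prints

```
adiabatic-basis MAE : 1.71e-04 eV
diabatic-basis  MAE : 4.04e-08 eV
ratio               : 0.0002
```

With 30 training geometries the direct adiabatic fit is limited by the cusp
at the avoided crossing (MAE ~2·10⁻⁴ eV on the 70 held-out geometries),
while fitting the corrected diabatic PEM elements and diagonalizing the
predictions is three to four orders of magnitude more accurate — the
surfaces being fitted are smooth lines.

A command-line surface wraps the same pipeline
(`pemlearn synth | diabatize | correct | reorder | sample-wigner | run`);
see `pemlearn --help`.

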