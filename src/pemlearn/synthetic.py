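"""Ground-truth coupled-surface generators for testing the whole pipeline.

Electronic-structure data are expensive; every algorithm here can instead be
exercised on synthetic diabatic models whose smooth potential-energy-matrix
elements are known in closed form.  A :class:`DiabaticModel` holds one smooth
scalar function (low-order polynomial plus Gaussian bumps) per independent
PEM element; diagonalizing the assembled U(x) produces adiabatic surfaces
with avoided crossings between coupled states and genuine crossings for
states whose couplings are identically zero.

On top of the clean model the generators reproduce the two defects the
correction step must repair: :func:`scramble` conjugates each geometry's PEM
by an independent random signed permutation (recording the truth), and
:func:`synth_multipoles` builds transition multipoles that rotate with the
adiabatic eigenvectors — including random per-state sign flips emulating the
arbitrary electronic wavefunction phases — so that property-matrix
diabatization of the synthetic records shows the realistic raw-output
behaviour.

Default scales (diabatic energy spacing ~0.5 eV, slopes ~0.35 eV per unit
coordinate, couplings ~0.1 eV on a [-1, 1]^dim box) mirror a thermally
sampled manifold of a small molecule: neighbouring excited states a few
tenths of an eV apart, diabatic couplings an order of magnitude smaller, and
crossing seams localized — surfaces swap energetic order only over a
minority of the sampled region, not half of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .assignment import SignedPermutation, apply_signed_permutation
from .diabatization import AdiabaticRecord


@dataclass(frozen=True)
class CrossingSpec:
    """Requested topology of the synthetic surfaces.

    ``coupling`` (eV) sets the scale of nonzero diabatic couplings (half the
    minimal adiabatic gap at a 2-state avoided crossing); ``uncoupled_state``
    names one state whose couplings are identically zero, so its adiabatic
    surface crosses the others exactly; ``diag_separation`` and
    ``diag_slope`` control where the diabatic surfaces cross.
    """

    coupling: float = 0.1
    uncoupled_state: int | None = None
    diag_separation: float = 0.5
    diag_slope: float = 0.35
    coupling_variation: float = 0.3  # relative smooth modulation of couplings


@dataclass(frozen=True)
class _Element:
    """One smooth PEM element: const + w.x + Gaussian bumps."""

    const: float
    linear: np.ndarray  # (dim,)
    bump_amps: np.ndarray  # (n_bumps,)
    bump_centers: np.ndarray  # (n_bumps, dim)
    bump_width: float = 0.8

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        val = self.const + x @ self.linear
        for amp, c in zip(self.bump_amps, self.bump_centers):
            val = val + amp * np.exp(-np.sum((x - c) ** 2, axis=1) / (2 * self.bump_width**2))
        return val


@dataclass(frozen=True)
class DiabaticModel:
    """Smooth n-state diabatic model on the [-1, 1]^dim box."""

    n_states: int
    dim: int
    elements: dict  # (i, j) i<=j -> _Element
    spec: CrossingSpec
    seed: int

    def pem(self, x: np.ndarray) -> np.ndarray:
        """U_true at a batch of coordinates; shape (n_points, n, n)."""
        x = np.atleast_2d(x)
        n = self.n_states
        U = np.zeros((x.shape[0], n, n))
        for (i, j), f in self.elements.items():
            v = f(x)
            U[:, i, j] = v
            U[:, j, i] = v
        return U


def make_diabatic_model(
    n_states: int, dim: int, crossing_spec: CrossingSpec | None = None, seed: int = 0
) -> DiabaticModel:
    """Build a seeded smooth diabatic model with the requested crossings.

    Diagonal elements are lines with alternating slopes (plus a mild seeded
    Gaussian bump) whose offsets are spaced by ``diag_separation``, so
    adjacent diabatic surfaces cross inside the box.  Couplings are smooth,
    nonzero functions of scale ``coupling`` — identically zero for the
    ``uncoupled_state``, whose adiabatic surface then crosses the others
    without interaction.
    """
    if n_states < 2 or dim < 1:
        raise ValueError("need n_states >= 2 and dim >= 1")
    spec = crossing_spec if crossing_spec is not None else CrossingSpec()
    if spec.uncoupled_state is not None and not 0 <= spec.uncoupled_state < n_states:
        raise ValueError("uncoupled_state index out of range")
    if spec.uncoupled_state is not None and n_states < 3 and spec.coupling != 0:
        # with 2 states one uncoupled state means no avoided crossing at all
        raise ValueError("an uncoupled state plus an avoided crossing needs >= 3 states")
    rng = np.random.default_rng(seed)
    elements: dict[tuple[int, int], _Element] = {}
    for i in range(n_states):
        direction = np.zeros(dim)
        direction[:] = rng.uniform(0.7, 1.0, size=dim) / np.sqrt(dim)
        slope = ((-1) ** i) * spec.diag_slope * direction
        bump = rng.uniform(-0.1, 0.1, size=1) * spec.diag_separation
        elements[(i, i)] = _Element(
            const=i * spec.diag_separation,
            linear=slope,
            bump_amps=bump,
            bump_centers=rng.uniform(-0.5, 0.5, size=(1, dim)),
        )
    for i in range(n_states):
        for j in range(i + 1, n_states):
            if spec.uncoupled_state in (i, j) or spec.coupling == 0:
                amp = 0.0
            else:
                amp = spec.coupling * rng.uniform(0.8, 1.2)
            mod = spec.coupling_variation * amp
            elements[(i, j)] = _Element(
                const=amp,
                linear=np.zeros(dim),
                bump_amps=np.array([mod]) if mod else np.zeros(1),
                bump_centers=rng.uniform(-0.5, 0.5, size=(1, dim)),
            )
    return DiabaticModel(n_states=n_states, dim=dim, elements=elements, spec=spec, seed=seed)


def avoided_crossing_1d(seed: int = 0, coupling: float = 0.02) -> DiabaticModel:
    """Two-state 1D preset with a narrowly avoided crossing.

    The small coupling makes the adiabatic surfaces nearly touch (minimal
    gap 2 x coupling) with a cusp-like transition much narrower than typical
    training-point spacing — the regime where direct adiabatic fitting
    degrades and the diabatic detour pays off.
    """
    return make_diabatic_model(2, 1, CrossingSpec(coupling=coupling), seed=seed)


def uncoupled_state_1d(seed: int = 0, coupling: float = 0.1) -> DiabaticModel:
    """Three-state 1D preset: two coupled states (avoided crossing) plus one
    state of different symmetry crossing them with zero coupling."""
    return make_diabatic_model(
        3, 1, CrossingSpec(coupling=coupling, uncoupled_state=2), seed=seed
    )


def sample_coords(dim: int, n: int, seed: int = 0) -> np.ndarray:
    """Uniform coordinates on the [-1, 1]^dim model box."""
    return np.random.default_rng(seed).uniform(-1, 1, size=(n, dim))


def evaluate_adiabatic(
    model: DiabaticModel, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(energies ascending, eigenvector matrices, U_true) at each coordinate.

    Eigenvector columns span the adiabatic states in the diabatic basis.
    """
    U = model.pem(coords)
    energies = np.empty((U.shape[0], model.n_states))
    vecs = np.empty_like(U)
    for k in range(U.shape[0]):
        w, v = np.linalg.eigh(U[k])
        energies[k] = w
        vecs[k] = v
    return energies, vecs, U


@dataclass(frozen=True)
class ScrambleRecord:
    """The signed permutations actually applied, for truth recovery."""

    applied: tuple[SignedPermutation, ...]
    sign_only: bool
    seed: int


def random_signed_permutation(
    rng: np.random.Generator, n: int, sign_only: bool = False
) -> SignedPermutation:
    """Uniform draw from the gauge-fixed signed permutations (first sign +1)."""
    perm = tuple(range(n)) if sign_only else tuple(int(i) for i in rng.permutation(n))
    signs = (1,) + tuple(int(s) for s in rng.choice([-1, 1], size=n - 1))
    return SignedPermutation(perm=perm, signs=signs)


def scramble(
    pems: np.ndarray, seed: int = 0, sign_only: bool = False
) -> tuple[np.ndarray, ScrambleRecord]:
    """Conjugate each geometry's PEM by an independent random signed
    permutation (or sign flips only), recording the ground truth."""
    pems = np.asarray(pems, dtype=float)
    rng = np.random.default_rng(seed)
    n = pems.shape[1]
    applied = []
    out = np.empty_like(pems)
    for g in range(pems.shape[0]):
        S = random_signed_permutation(rng, n, sign_only=sign_only)
        out[g] = apply_signed_permutation(pems[g], S)
        applied.append(S)
    return out, ScrambleRecord(applied=tuple(applied), sign_only=sign_only, seed=seed)


# -- synthetic transition multipoles ----------------------------------------

# orthonormal (Frobenius) symmetric 3x3 basis tensors for quadrupole channels
_SQRT2 = np.sqrt(2.0)
_QUAD_BASIS = [
    np.diag([1.0, 0.0, 0.0]),
    np.diag([0.0, 1.0, 0.0]),
    np.diag([0.0, 0.0, 1.0]),
    np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]) / _SQRT2,
    np.array([[0, 0, 1], [0, 0, 0], [1, 0, 0]]) / _SQRT2,
    np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]]) / _SQRT2,
]


@dataclass(frozen=True)
class MultipoleSpec:
    """Smooth diabatic multipole functions, mutually distinguishable.

    Each diabatic state i carries a dipole along a fixed direction (states
    0-2 use the Cartesian axes) and, beyond three states, a distinct
    quadrupole basis tensor; magnitudes are distinct and modulated by a
    smooth tanh factor of amplitude ``variation`` so the property-matrix
    eigenvalues stay separated everywhere on the box.
    """

    base_magnitude: float = 1.0
    magnitude_step: float = 0.4
    variation: float = 0.15
    include_quadrupoles: bool = True
    include_octupoles: bool = False


def _diabatic_multipoles(
    n_states: int, spec: MultipoleSpec, x: np.ndarray, rng_dirs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point diabatic multipoles (dipoles, quadrupoles, octupoles)."""
    n_pts = x.shape[0]
    dip = np.zeros((n_pts, n_states, 3))
    quad = np.zeros((n_pts, n_states, 3, 3))
    octu = np.zeros((n_pts, n_states, 3, 3, 3))
    for i in range(n_states):
        mag = spec.base_magnitude + i * spec.magnitude_step
        smooth = 1.0 + spec.variation * np.tanh(x @ rng_dirs[i])
        if i < 3:
            axis = np.zeros(3)
            axis[i] = 1.0
            dip[:, i] = smooth[:, None] * mag * axis
        else:
            if not spec.include_quadrupoles:
                raise ValueError(
                    "more than 3 states need quadrupole channels to stay distinguishable"
                )
            B = _QUAD_BASIS[i - 3]
            quad[:, i] = smooth[:, None, None] * mag * B
        if spec.include_octupoles:
            T = np.zeros((3, 3, 3))
            T[i % 3, (i + 1) % 3, (i + 2) % 3] = 1.0
            octu[:, i] = (0.3 * mag * smooth)[:, None, None, None] * T
    return dip, quad, octu


def synth_multipoles(
    model: DiabaticModel,
    coords: np.ndarray,
    spec: MultipoleSpec | None = None,
    seed: int = 0,
) -> tuple[list[AdiabaticRecord], np.ndarray]:
    """Adiabatic records (energies + ground-state transition multipoles) for a
    batch of coordinates, plus the true PEM stack.

    Adiabatic multipoles are the eigenvector transform of the smooth diabatic
    ones, mu_0a = sum_i C_ia mu_i^d; each adiabatic state is additionally
    given a random +-1 phase (seeded), emulating the arbitrary signs of
    electronic wavefunctions that property-based diabatization inherits.
    """
    spec = spec if spec is not None else MultipoleSpec()
    coords = np.atleast_2d(coords)
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(model.n_states, model.dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    energies, vecs, U_true = evaluate_adiabatic(model, coords)
    dip_d, quad_d, oct_d = _diabatic_multipoles(model.n_states, spec, coords, dirs)
    records = []
    for g in range(coords.shape[0]):
        C = vecs[g]  # columns: adiabatic states in the diabatic basis
        phases = rng.choice([-1.0, 1.0], size=model.n_states)
        dip = np.einsum("ia,ix->ax", C, dip_d[g]) * phases[:, None]
        quad = np.einsum("ia,ixy->axy", C, quad_d[g]) * phases[:, None, None]
        octu = np.einsum("ia,ixyz->axyz", C, oct_d[g]) * phases[:, None, None, None]
        records.append(
            AdiabaticRecord(
                energies=energies[g],
                dipoles=dip,
                quadrupoles=quad if spec.include_quadrupoles else None,
                octupoles=octu if spec.include_octupoles else None,
                geometry_id=g,
            )
        )
    return records, U_true


# -- toy CIS wavefunction bundles -------------------------------------------


@dataclass(frozen=True)
class ToyCISSpec:
    """Path layout for the toy wavefunction bundle.

    States keep an essentially constant electronic character (dominant
    excitation) with a mild smooth mixing of amplitude ``mixing``; past
    ``swap_point`` on the [0, 1] path the storage (energy) order of states 0
    and 1 is exchanged, the defect character-based clustering must detect.
    ``mo_drift`` smoothly rotates the virtual orbitals along the path.
    """

    swap_point: float = 0.5
    mixing: float = 0.15
    mo_drift: float = 0.2


@dataclass(frozen=True)
class ToyCISBundle:
    wavefunctions: list  # flat list of CISWavefunction, geometry-major
    true_labels: np.ndarray  # character cluster of each stored state
    path: np.ndarray  # path parameter per geometry
    n_states: int

    def ao_overlaps(self, g1: int, g2: int) -> np.ndarray:
        n_ao = self.wavefunctions[0].mo_coefficients.shape[0]
        return np.eye(n_ao)


def make_toy_cis(
    n_geoms: int, n_states: int = 2, drift_spec: ToyCISSpec | None = None, seed: int = 0
) -> ToyCISBundle:
    """CIS states drifting smoothly along a 1D path, with a mid-path swap of
    the stored (energy) order of the two lowest states.

    MOs are orthonormal in a shared AO frame (AO cross overlaps are the
    identity); each state's character is a distinct dominant single
    excitation out of the HOMO.
    """
    from .overlaps import CISWavefunction

    spec = drift_spec if drift_spec is not None else ToyCISSpec()
    if n_states < 2:
        raise ValueError("need at least two states")
    n_occ = 2
    n_virt = n_states + 1
    n_mo = n_occ + n_virt
    t = np.linspace(0.0, 1.0, n_geoms)
    excitations = tuple((n_occ - 1, n_occ + v) for v in range(n_virt))
    wavefunctions = []
    labels = []
    for g, tg in enumerate(t):
        # smooth drift in the virtual block keeps cross-geometry overlaps < 1
        phi = spec.mo_drift * tg
        C = np.eye(n_mo)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        C[np.ix_([n_mo - 2, n_mo - 1], [n_mo - 2, n_mo - 1])] = rot
        # orthonormal CI vectors: rows of exp(theta * A) for a fixed skew
        # generator A — state i stays dominated by configuration i while all
        # states mix smoothly and remain exactly orthonormal
        theta = spec.mixing * np.sin(2 * np.pi * tg)
        skew = np.zeros((n_virt, n_virt))
        for i in range(n_virt - 1):
            skew[i, i + 1], skew[i + 1, i] = 1.0, -1.0
        mix = expm(theta * skew)
        states = [(i, mix[i]) for i in range(n_states)]
        order = list(range(n_states))
        if tg >= spec.swap_point:
            order[0], order[1] = order[1], order[0]
        for slot, idx in enumerate(order):
            character, coeffs = states[idx]
            wavefunctions.append(
                CISWavefunction(
                    ci_coefficients=coeffs,
                    excitations=excitations,
                    mo_coefficients=C,
                    n_occ=n_occ,
                    geometry_id=g,
                    state_id=slot,
                )
            )
            labels.append(character)
    return ToyCISBundle(
        wavefunctions=wavefunctions,
        true_labels=np.array(labels),
        path=t,
        n_states=n_states,
    )
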