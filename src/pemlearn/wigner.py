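"""Thermal Wigner sampling of nuclear geometries from harmonic normal modes.

At temperature T the harmonic Wigner quasiprobability density of each normal
mode is a Gaussian in both the mode coordinate q_i and momentum p_i with

    Var(q_i) = coth(hbar w_i / (2 k_B T)) / (2 mu_i w_i)
    Var(p_i) = (mu_i w_i / 2) * coth(hbar w_i / (2 k_B T))

in atomic units (hbar = 1); at T = 0 the coth factor is 1 (ground-state
Wigner function), and for k_B T >> w_i it approaches the classical
equipartition result Var(q_i) = k_B T / (mu_i w_i^2).  Modes are sampled
independently and Cartesian geometries reconstructed from the reference
structure plus mode displacements; momenta are drawn too but only the
geometries feed the regression pipeline.

Frequencies are accepted in cm^-1 and converted internally; zero-frequency
(translation/rotation) modes must be excluded before sampling, and imaginary
frequencies are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMU_TO_ME, ATOMIC_MASSES, BOHR_TO_ANGSTROM, CM1_TO_AU, KB_AU
from .representations import Geometry


@dataclass(frozen=True)
class NormalModeSet:
    """Harmonic vibrational analysis output for one reference structure.

    ``frequencies_cm1``: mode wavenumbers (cm^-1, positive); ``reduced_masses``
    in dalton; ``displacements``: (n_modes, n_atoms, 3) Cartesian mode vectors,
    orthonormal in mass-weighted coordinates; ``reference``: the equilibrium
    geometry (Å); ``masses`` per atom in dalton (element defaults if omitted).
    """

    frequencies_cm1: np.ndarray
    reduced_masses: np.ndarray
    displacements: np.ndarray
    reference: Geometry
    masses: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.frequencies_cm1, dtype=float)
        mu = np.asarray(self.reduced_masses, dtype=float)
        L = np.asarray(self.displacements, dtype=float)
        if np.any(f < 0):
            raise ValueError(
                "imaginary-frequency mode present; exclude it before sampling "
                "(transition states cannot be Wigner-sampled harmonically)"
            )
        if np.any(f == 0):
            raise ValueError("zero-frequency (translation/rotation) modes must be excluded")
        if L.shape != (f.size, self.reference.n_atoms, 3):
            raise ValueError("displacements must have shape (n_modes, n_atoms, 3)")
        if mu.shape != f.shape or np.any(mu <= 0):
            raise ValueError("one positive reduced mass per mode required")
        masses = self.masses
        if masses is None:
            masses = np.array([ATOMIC_MASSES[el] for el in self.reference.atom_labels])
        masses = np.asarray(masses, dtype=float)
        # orthonormality in mass-weighted coordinates
        mw = L * np.sqrt(masses)[None, :, None]
        mw = mw.reshape(f.size, -1)
        gram = mw @ mw.T
        if not np.allclose(gram, np.eye(f.size), atol=1e-6):
            raise ValueError("displacement vectors not orthonormal in mass-weighted coordinates")
        object.__setattr__(self, "frequencies_cm1", f)
        object.__setattr__(self, "reduced_masses", mu)
        object.__setattr__(self, "displacements", L)
        object.__setattr__(self, "masses", masses)

    @property
    def n_modes(self) -> int:
        return self.frequencies_cm1.size

    def omega_au(self) -> np.ndarray:
        return self.frequencies_cm1 * CM1_TO_AU

    def mu_au(self) -> np.ndarray:
        return self.reduced_masses * AMU_TO_ME


def wigner_variances(modes: NormalModeSet, T: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form thermal variances of (q_i, p_i) in atomic units."""
    if T < 0:
        raise ValueError("temperature must be >= 0")
    omega = modes.omega_au()
    mu = modes.mu_au()
    if T == 0:
        coth = np.ones_like(omega)
    else:
        coth = 1.0 / np.tanh(omega / (2.0 * KB_AU * T))
    var_q = coth / (2.0 * mu * omega)
    var_p = 0.5 * mu * omega * coth
    return var_q, var_p


@dataclass(frozen=True)
class WignerSample:
    """One ensemble draw: geometries (Å) plus mode coordinates/momenta (a.u.)."""

    geometries: tuple[Geometry, ...]
    q: np.ndarray  # (n_samples, n_modes)
    p: np.ndarray  # (n_samples, n_modes)
    temperature: float
    seed: int


def sample_wigner(modes: NormalModeSet, T: float, n: int, seed: int = 0) -> WignerSample:
    """Draw n geometries (and momenta) from the thermal harmonic Wigner density.

    Deterministic given ``seed``.  Mode coordinates are converted to Cartesian
    displacements via dx_A = sqrt(mu_i / m_A) * L_(i,A) * q_i (all in atomic
    units, then back to Å).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    var_q, var_p = wigner_variances(modes, T)
    rng = np.random.default_rng(seed)
    q = rng.normal(0.0, np.sqrt(var_q), size=(n, modes.n_modes))
    p = rng.normal(0.0, np.sqrt(var_p), size=(n, modes.n_modes))
    masses_me = modes.masses * AMU_TO_ME
    mu = modes.mu_au()
    # (n_modes, n_atoms, 3) Cartesian displacement per unit q_i, atomic units
    per_q = np.sqrt(mu)[:, None, None] * modes.displacements / np.sqrt(masses_me)[None, :, None]
    ref_bohr = modes.reference.coords / BOHR_TO_ANGSTROM
    geometries = []
    for k in range(n):
        disp = np.tensordot(q[k], per_q, axes=1)  # bohr
        coords = (ref_bohr + disp) * BOHR_TO_ANGSTROM
        geometries.append(
            Geometry(atom_labels=modes.reference.atom_labels, coords=coords, id=k)
        )
    return WignerSample(geometries=tuple(geometries), q=q, p=p, temperature=T, seed=seed)


def mode_energies(modes: NormalModeSet, sample: WignerSample) -> np.ndarray:
    """Harmonic energy per draw and mode, E_i = p_i^2/(2 mu_i) + mu_i w_i^2 q_i^2 / 2.

    Sampler diagnostic: the ensemble mean per mode should approach
    (w_i / 2) coth(w_i / (2 k_B T)) — the zero-point energy at T = 0 and the
    equipartition value k_B T in the classical limit.
    """
    omega = modes.omega_au()
    mu = modes.mu_au()
    return sample.p**2 / (2.0 * mu) + 0.5 * mu * omega**2 * sample.q**2


def expected_mode_energy(modes: NormalModeSet, T: float) -> np.ndarray:
    """(w_i / 2) coth(w_i / (2 k_B T)) per mode, atomic units."""
    omega = modes.omega_au()
    if T == 0:
        return omega / 2.0
    return 0.5 * omega / np.tanh(omega / (2.0 * KB_AU * T))
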