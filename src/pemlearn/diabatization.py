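"""Property-based diabatization from ground-state transition multipoles.

For each geometry the adiabatic energies V_a and the transition multipoles
from the ground state (dipole mu_0a, quadrupole Q_0a, octupole O_0a) define a
symmetric property matrix

    tD  : P_ab = mu_0a . mu_0b
    tDQ : P_ab = mu_0a . mu_0b + w_Q <Q_0a, Q_0b>_F
    tDQO: P_ab = tDQ + w_O <O_0a, O_0b>_F

(<.,.>_F is the Frobenius inner product over the full Cartesian tensors; all
weights default to 1).  Diagonalizing P "unblends" the states: its
eigenvector matrix T transforms the diagonal adiabatic matrix V into the
diabatic potential-energy matrix U = T^T V T, whose diagonal holds diabatic
energies and off-diagonal holds diabatic couplings.

Raw per-geometry outputs carry two defects that downstream correction must
repair: the eigenvector order (hence diabatic state labels) is not
consistent across geometries, and electronic wavefunction signs randomize
the coupling signs.  A fixed eigenvector convention (descending eigenvalue,
largest-magnitude component positive) makes individual runs repeatable but
does not remove either defect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

LEVELS = ("tD", "tDQ", "tDQO")


@dataclass(frozen=True)
class AdiabaticRecord:
    """One geometry's excited-state manifold: energies plus transition multipoles.

    Energies in eV (ascending); multipoles in atomic units.  The ground state
    is not part of the manifold; multipoles are matrix elements between the
    ground state and each manifold state.
    """

    energies: np.ndarray  # (n,), eV, ascending
    dipoles: np.ndarray  # (n, 3), a.u.
    quadrupoles: np.ndarray | None = None  # (n, 3, 3)
    octupoles: np.ndarray | None = None  # (n, 3, 3, 3)
    geometry_id: int = 0

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        d = np.asarray(self.dipoles, dtype=float)
        if np.any(np.diff(e) < -1e-12):
            raise ValueError("adiabatic energies must be ascending")
        if d.shape != (e.size, 3):
            raise ValueError("need one 3-vector transition dipole per state")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "dipoles", d)
        for name, shape in (("quadrupoles", (e.size, 3, 3)), ("octupoles", (e.size, 3, 3, 3))):
            t = getattr(self, name)
            if t is not None:
                t = np.asarray(t, dtype=float)
                if t.shape != shape:
                    raise ValueError(f"{name} must have shape {shape}")
                if not np.all(np.isfinite(t)):
                    raise ValueError(f"non-finite {name}")
                object.__setattr__(self, name, t)

    @property
    def n_states(self) -> int:
        return self.energies.size


@dataclass(frozen=True)
class PropertyMatrix:
    P: np.ndarray
    level: str
    w_q: float = 1.0
    w_o: float = 1.0

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("property matrix must be symmetric")
        object.__setattr__(self, "P", P)


@dataclass(frozen=True)
class PEM:
    """Diabatic potential-energy matrix U with its orthogonal transform T.

    U = T^T V T, V = diag(adiabatic energies); eigenvalues of U are exactly
    the adiabatic energies.  ``degenerate`` flags property-matrix eigenvalue
    degeneracy, where the transformation is ill-defined within the subspace.
    """

    U: np.ndarray
    T: np.ndarray
    geometry_id: int = 0
    degenerate: bool = False

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if not np.allclose(U, U.T, atol=1e-10):
            raise ValueError("U must be symmetric")
        if not np.allclose(T.T @ T, np.eye(T.shape[0]), atol=1e-10):
            raise ValueError("T must be orthogonal")
        object.__setattr__(self, "U", 0.5 * (U + U.T))
        object.__setattr__(self, "T", T)


def property_matrix(
    record: AdiabaticRecord, level: str = "tD", w_q: float = 1.0, w_o: float = 1.0
) -> PropertyMatrix:
    """Assemble the tD / tDQ / tDQO property matrix (exactly symmetric)."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    P = record.dipoles @ record.dipoles.T
    if level in ("tDQ", "tDQO"):
        if record.quadrupoles is None:
            raise ValueError(f"level {level} requires transition quadrupoles")
        Q = record.quadrupoles.reshape(record.n_states, -1)
        P = P + w_q * (Q @ Q.T)
    if level == "tDQO":
        if record.octupoles is None:
            raise ValueError("level tDQO requires transition octupoles")
        O = record.octupoles.reshape(record.n_states, -1)
        P = P + w_o * (O @ O.T)
    P = 0.5 * (P + P.T)
    return PropertyMatrix(P=P, level=level, w_q=w_q, w_o=w_o)


def eigenvector_convention(eigvals: np.ndarray, eigvecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector matrix: columns by descending eigenvalue,
    each column's largest-magnitude entry made positive."""
    order = np.argsort(eigvals)[::-1]
    T = eigvecs[:, order]
    for c in range(T.shape[1]):
        k = np.argmax(np.abs(T[:, c]))
        if T[k, c] < 0:
            T[:, c] = -T[:, c]
    return T


def diabatize(
    record: AdiabaticRecord, P: PropertyMatrix, degeneracy_rtol: float = 1e-8
) -> PEM:
    """U = T^T V T with T the property-matrix eigenvectors.

    Degenerate P eigenvalues (relative gap below ``degeneracy_rtol``) leave
    the transformation ill-defined in that subspace; the PEM is flagged and a
    warning emitted, but the eigendecomposition is used as returned.
    """
    eigvals, eigvecs = np.linalg.eigh(P.P)
    scale = max(np.max(np.abs(eigvals)), 1e-300)
    degenerate = bool(np.any(np.abs(np.diff(eigvals)) / scale < degeneracy_rtol))
    if degenerate:
        warnings.warn(
            f"geometry {record.geometry_id}: degenerate property-matrix eigenvalues; "
            "diabatic transformation ill-defined in the degenerate subspace"
        )
    T = eigenvector_convention(eigvals, eigvecs)
    U = T.T @ np.diag(record.energies) @ T
    U = 0.5 * (U + U.T)
    return PEM(U=U, T=T, geometry_id=record.geometry_id, degenerate=degenerate)


def adiabatize(U: np.ndarray | PEM) -> tuple[np.ndarray, np.ndarray]:
    """Ascending eigenvalues (adiabatic energies) and eigenvectors of U."""
    M = U.U if isinstance(U, PEM) else np.asarray(U, dtype=float)
    return np.linalg.eigh(0.5 * (M + M.T))


def diabatize_ensemble(
    records: list[AdiabaticRecord], level: str = "tD", w_q: float = 1.0, w_o: float = 1.0
) -> list[PEM]:
    """Raw per-geometry diabatization of a whole ensemble."""
    return [diabatize(r, property_matrix(r, level, w_q, w_o)) for r in records]
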