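"""Wavefunction-overlap distances and silhouette clustering of states.

An independent, wavefunction-based benchmark for the reordering problem:
electronic states tend to keep their character through crossings, so the
absolute wavefunction overlap is a natural similarity between states of
different nuclear configurations, and d = 1 - |overlap| a distance in [0, 1].

Wavefunctions are CIS-type expansions over singly excited, spin-adapted
singlet configurations (the form TDDFT/TDA amplitudes take).  The overlap of
two Slater determinants is a determinant of occupied-MO cross overlaps
(per spin block), the MO cross overlaps being C1^T S_AO C2; the state
overlap is the CI-coefficient-weighted double sum over determinant pairs.

States of all geometries are then clustered by direct maximization of the
mean silhouette coefficient, under the constraint that the states of any one
geometry occupy distinct clusters: sweeping geometry by geometry, a matrix
of provisional silhouettes (state s placed in cluster c, all else fixed)
feeds a linear sum assignment, repeated until no assignment changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass(frozen=True)
class CISWavefunction:
    """Singlet CIS expansion: spin-adapted singly excited configurations.

    ``excitations`` lists (occupied, virtual) MO index pairs; ``ci_coefficients``
    the matching expansion coefficients (normalized).  ``mo_coefficients`` is
    the full MO-over-AO matrix (columns = MOs, occupied first).
    """

    ci_coefficients: np.ndarray
    excitations: tuple[tuple[int, int], ...]
    mo_coefficients: np.ndarray
    n_occ: int
    geometry_id: int = 0
    state_id: int = 0

    def __post_init__(self):
        c = np.asarray(self.ci_coefficients, dtype=float)
        C = np.asarray(self.mo_coefficients, dtype=float)
        if c.size != len(self.excitations):
            raise ValueError("one coefficient per excitation required")
        norm = float(np.sum(c**2))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"CIS expansion not normalized (sum c^2 = {norm})")
        for occ, virt in self.excitations:
            if not (0 <= occ < self.n_occ <= virt < C.shape[1]):
                raise ValueError(f"invalid excitation ({occ} -> {virt})")
        object.__setattr__(self, "ci_coefficients", c)
        object.__setattr__(self, "mo_coefficients", C)
        object.__setattr__(self, "excitations", tuple(map(tuple, self.excitations)))


def determinant_overlap(mo_overlap_block: np.ndarray) -> float:
    """Overlap of two same-spin determinants: det of their occupied-MO cross
    overlaps."""
    block = np.asarray(mo_overlap_block, dtype=float)
    if block.ndim != 2 or block.shape[0] != block.shape[1]:
        raise ValueError("MO overlap block must be square")
    return float(np.linalg.det(block))


def _occupied_set(n_occ: int, excitation: tuple[int, int] | None) -> list[int]:
    occ = list(range(n_occ))
    if excitation is not None:
        i, a = excitation
        occ[occ.index(i)] = a
    return occ


def cis_overlap(
    wf1: CISWavefunction, wf2: CISWavefunction, ao_cross_overlap: np.ndarray
) -> float:
    """Overlap of two CIS states, possibly at different geometries.

    S_MO = C1^T S_AO C2; each spin-adapted configuration pair contributes

        (1/2) [ <k_a|l_a> + <k_a|l_b> + <k_b|l_a> + <k_b|l_b> ]

    where each bracket is a product of an alpha- and a beta-block determinant
    over the occupied orbitals of the two determinants.  All occupied
    orbitals of the expansion are included (no frozen core).
    """
    S_AO = np.asarray(ao_cross_overlap, dtype=float)
    C1, C2 = wf1.mo_coefficients, wf2.mo_coefficients
    if S_AO.shape != (C1.shape[0], C2.shape[0]):
        raise ValueError("AO cross-overlap dimensions do not match MO coefficients")
    if wf1.n_occ != wf2.n_occ:
        raise ValueError("occupied-orbital counts differ")
    S_MO = C1.T @ S_AO @ C2
    n_occ = wf1.n_occ

    def block_det(exc1, exc2) -> float:
        rows = _occupied_set(n_occ, exc1)
        cols = _occupied_set(n_occ, exc2)
        return determinant_overlap(S_MO[np.ix_(rows, cols)])

    ground = block_det(None, None)
    total = 0.0
    for ck, exc_k in zip(wf1.ci_coefficients, wf1.excitations):
        exc_k_ground = block_det(exc_k, None)
        for cl, exc_l in zip(wf2.ci_coefficients, wf2.excitations):
            same_spin = block_det(exc_k, exc_l) * ground
            cross_spin = exc_k_ground * block_det(None, exc_l)
            total += ck * cl * (same_spin + cross_spin)
    return total


def state_distance(overlap_value: float) -> float:
    """d = 1 - |overlap|, phase-insensitive, clipped to [0, 1].

    Overlap magnitudes beyond 1 + 1e-8 signal inconsistent inputs and raise.
    """
    mag = abs(float(overlap_value))
    if mag > 1.0 + 1e-8:
        raise ValueError(f"|overlap| = {mag} exceeds 1; inconsistent wavefunction inputs")
    return 1.0 - min(mag, 1.0)


@dataclass(frozen=True)
class StateDistanceMatrix:
    """Pairwise 1-|overlap| distances over all (geometry, state) points."""

    d: np.ndarray
    points: tuple[tuple[int, int], ...]  # point index -> (geometry_id, state_id)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.points), len(self.points)):
            raise ValueError("distance matrix shape must match point count")
        if not np.allclose(d, d.T, atol=1e-12) or np.any(np.abs(np.diag(d)) > 1e-12):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "points", tuple(map(tuple, self.points)))

    @property
    def geometry_ids(self) -> list[int]:
        return sorted({g for g, _ in self.points})

    def indices_of_geometry(self, geometry_id: int) -> list[int]:
        return [k for k, (g, _) in enumerate(self.points) if g == geometry_id]


def distance_matrix_from_wavefunctions(
    wavefunctions: list[CISWavefunction],
    ao_overlaps,
) -> StateDistanceMatrix:
    """Assemble all pairwise state distances; ``ao_overlaps(g1, g2)`` returns
    the AO cross-overlap matrix for a geometry pair."""
    n = len(wavefunctions)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            wi, wj = wavefunctions[i], wavefunctions[j]
            ov = cis_overlap(wi, wj, ao_overlaps(wi.geometry_id, wj.geometry_id))
            d[i, j] = d[j, i] = state_distance(ov)
    points = tuple((w.geometry_id, w.state_id) for w in wavefunctions)
    return StateDistanceMatrix(d=d, points=points)


def silhouette_mean(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b - a) / max(a, b) over all points.

    a(i): mean distance to own-cluster peers (excluding self); b(i): minimum
    over other clusters of the mean distance to that cluster.  Points in
    singleton clusters score 0 by convention.
    """
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    s_total = 0.0
    for i in range(len(labels)):
        own = (labels == labels[i]) & (np.arange(len(labels)) != i)
        if not own.any():
            continue  # singleton: s = 0
        a = d[i, own].mean()
        b = min(
            d[i, labels == other].mean() for other in np.unique(labels) if other != labels[i]
        )
        s_total += (b - a) / max(a, b)
    return s_total / len(labels)


@dataclass(frozen=True)
class SilhouetteClustering:
    labels: np.ndarray
    mean_silhouette: float
    n_sweeps: int
    converged: bool

    def __post_init__(self):
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))


def _check_constraint(dmat: StateDistanceMatrix, labels: np.ndarray) -> None:
    for gid in dmat.geometry_ids:
        idx = dmat.indices_of_geometry(gid)
        if len({int(labels[k]) for k in idx}) != len(idx):
            raise ValueError(f"geometry {gid}: states share a cluster in the initial labels")


def silhouette_cluster(
    dmat: StateDistanceMatrix,
    init_labels: np.ndarray | None = None,
    max_sweeps: int = 50,
) -> SilhouetteClustering:
    """Constrained clustering by direct silhouette maximization.

    Default initialization assigns each geometry's states to clusters in
    their stored (energy) order.  Each sweep visits every geometry, scores
    every (state, cluster) provisional placement by that state's silhouette
    with all other points fixed, solves the maximizing linear sum assignment,
    and commits immediately.  Stops on a no-change sweep.
    """
    n_points = len(dmat.points)
    geometry_ids = dmat.geometry_ids
    n_clusters = len(dmat.indices_of_geometry(geometry_ids[0]))
    if init_labels is None:
        labels = np.empty(n_points, dtype=int)
        for gid in geometry_ids:
            idx = dmat.indices_of_geometry(gid)
            order = np.argsort([dmat.points[k][1] for k in idx])
            for c, pos in enumerate(order):
                labels[idx[pos]] = c
    else:
        labels = np.asarray(init_labels, dtype=int).copy()
        _check_constraint(dmat, labels)
    d = dmat.d
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        changed = 0
        for gid in geometry_ids:
            idx = dmat.indices_of_geometry(gid)
            score = np.zeros((len(idx), n_clusters))
            for r, k in enumerate(idx):
                for c in range(n_clusters):
                    trial = labels.copy()
                    trial[k] = c
                    own = (trial == c) & (np.arange(n_points) != k)
                    if not own.any():
                        score[r, c] = 0.0
                        continue
                    a = d[k, own].mean()
                    b = min(
                        d[k, trial == other].mean()
                        for other in range(n_clusters)
                        if other != c and (trial == other).any()
                    )
                    score[r, c] = (b - a) / max(a, b)
            rows, cols = linear_sum_assignment(-score)
            for r, c in zip(rows, cols):
                if labels[idx[r]] != c:
                    changed += 1
                    labels[idx[r]] = c
        if changed == 0:
            converged = True
            break
    return SilhouetteClustering(
        labels=labels,
        mean_silhouette=silhouette_mean(d, labels),
        n_sweeps=sweeps,
        converged=converged,
    )
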