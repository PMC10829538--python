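"""Geometry canonicalization, ensemble alignment and molecular features.

Diabatic potential-energy matrices are not invariant under permutation of
chemically equivalent nuclei or under inversion, so before any regression the
geometry ensemble is brought into a canonical form: equivalent atoms are
reordered by distance to a reference atom (e.g. the two formaldehyde
hydrogens so that r(C-H1) < r(C-H2)), the molecule is reflected so that a
designated atom always lies on the same side of a declared plane, and all
frames are rigidly superimposed onto one reference frame (Kabsch, proper
rotations only).

The regression feature vector is the vector of normalized inverted
internuclear distances

    x_(i,j) = r_ref(i,j) / r(i,j),   i < j,

which is dimensionless, exactly invariant under rigid motions and inversion,
and maps the reference geometry to the all-ones vector.  Reference distances
are by default the ensemble means of each pair distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class Geometry:
    """A single molecular frame: element symbols plus Cartesian coordinates in Å."""

    atom_labels: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å
    id: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if coords.shape[0] != len(self.atom_labels):
            raise ValueError("label/coordinate count mismatch")
        if coords.shape[0] < 2:
            raise ValueError("geometry needs at least two atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "atom_labels", tuple(self.atom_labels))
        object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)


@dataclass(frozen=True)
class FeatureVector:
    """Normalized inverted internuclear distances, canonical (i<j) pair order."""

    values: np.ndarray
    pair_order: tuple[tuple[int, int], ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(values) != len(self.pair_order):
            raise ValueError("feature length must match pair count")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("features must be strictly positive and finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pair_order", tuple(map(tuple, self.pair_order)))


@dataclass(frozen=True)
class EquivalenceSpec:
    """Which atoms are chemically equivalent and how inversion is fixed.

    ``groups`` are disjoint index sets of equivalent atoms, each sorted by
    ascending distance to ``reference_atom`` during canonicalization.
    ``plane`` (three atom indices) and ``test_atom`` define the inversion
    convention: the geometry is reflected through the plane whenever the test
    atom's signed distance to it is negative.
    """

    groups: tuple[tuple[int, ...], ...] = ()
    reference_atom: int = 0
    plane: tuple[int, int, int] | None = None
    test_atom: int | None = None

    def __post_init__(self):
        seen: set[int] = set()
        for g in self.groups:
            if seen & set(g):
                raise ValueError("equivalence groups must be disjoint")
            seen |= set(g)
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))


class InvalidSpecError(ValueError):
    pass


class DegeneratePlaneError(ValueError):
    pass


def canonical_pairs(n_atoms: int) -> tuple[tuple[int, int], ...]:
    """Lexicographic (i<j) atom pairs."""
    return tuple((i, j) for i in range(n_atoms) for j in range(i + 1, n_atoms))


def pair_distances(geom: Geometry) -> np.ndarray:
    """Distances for the canonical pair list, Å."""
    i, j = np.array(canonical_pairs(geom.n_atoms)).T
    return np.linalg.norm(geom.coords[i] - geom.coords[j], axis=1)


def canonicalize_permutation(geom: Geometry, spec: EquivalenceSpec) -> Geometry:
    """Reorder each equivalence group by ascending distance to the reference atom.

    Ties are broken by original atom index, making the operation deterministic
    and idempotent.  Raises :class:`InvalidSpecError` if a group mixes
    elements.
    """
    coords = geom.coords.copy()
    order = np.arange(geom.n_atoms)
    for group in spec.groups:
        elements = {geom.atom_labels[i] for i in group}
        if len(elements) > 1:
            raise InvalidSpecError(f"equivalence group {group} mixes elements {elements}")
        ref = geom.coords[spec.reference_atom]
        dists = [np.linalg.norm(geom.coords[i] - ref) for i in group]
        ranked = sorted(zip(dists, group))  # ties -> lower original index first
        for slot, (_, src) in zip(group, ranked):
            order[slot] = src
    coords = geom.coords[order]
    return replace(geom, coords=coords)


def _plane_normal(coords: np.ndarray, plane: tuple[int, int, int]) -> np.ndarray:
    a, b, c = (coords[k] for k in plane)
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise DegeneratePlaneError("plane atoms are collinear")
    return n / norm


def signed_plane_distance(geom: Geometry, spec: EquivalenceSpec) -> float:
    """Signed distance of the test atom to the declared plane."""
    if spec.plane is None or spec.test_atom is None:
        raise InvalidSpecError("spec declares no inversion plane/test atom")
    n = _plane_normal(geom.coords, spec.plane)
    return float(np.dot(geom.coords[spec.test_atom] - geom.coords[spec.plane[0]], n))


def canonicalize_inversion(geom: Geometry, spec: EquivalenceSpec) -> Geometry:
    """Reflect the geometry through the declared plane if the test atom lies
    on the negative side; afterwards its signed distance is >= 0."""
    d = signed_plane_distance(geom, spec)
    if d >= 0:
        return geom
    n = _plane_normal(geom.coords, spec.plane)
    origin = geom.coords[spec.plane[0]]
    rel = geom.coords - origin
    reflected = rel - 2.0 * np.outer(rel @ n, n) + origin
    return replace(geom, coords=reflected)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimizing ||mobile @ R.T + t - target||.

    Reflections are excluded (det R = +1); handedness changes are the job of
    :func:`canonicalize_inversion`, never of alignment.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    R, _rmsd = Rotation.align_vectors(target - tc, mobile - mc)
    Rm = R.as_matrix()  # scipy returns a proper rotation
    t = tc - mc @ Rm.T
    return Rm, t


def align_ensemble(ensemble: list[Geometry], reference_index: int = 0) -> list[Geometry]:
    """Rigidly superimpose every frame onto the reference frame.

    Each geometry is rotated (proper rotation) and translated to minimize the
    mean squared deviation of atomic centres from the reference; the reference
    itself is returned unchanged.
    """
    ref = ensemble[reference_index]
    labels = ref.atom_labels
    out = []
    for geom in ensemble:
        if geom.atom_labels != labels:
            raise ValueError(f"geometry {geom.id}: atom labels differ from reference")
        if geom is ref:
            out.append(geom)
            continue
        R, t = kabsch(geom.coords, ref.coords)
        out.append(replace(geom, coords=geom.coords @ R.T + t))
    return out


def msd(a: Geometry, b: Geometry) -> float:
    """Mean squared deviation of atomic centres, Å²."""
    return float(np.mean(np.sum((a.coords - b.coords) ** 2, axis=1)))


def ensemble_reference_distances(ensemble: list[Geometry]) -> np.ndarray:
    """Arithmetic mean of each canonical pair distance over the ensemble."""
    if not ensemble:
        raise ValueError("empty ensemble")
    return np.mean([pair_distances(g) for g in ensemble], axis=0)


def featurize(geom: Geometry, ref_distances: np.ndarray) -> FeatureVector:
    """Normalized inverted distances x_(i,j) = r_ref(i,j)/r(i,j)."""
    pairs = canonical_pairs(geom.n_atoms)
    ref = np.asarray(ref_distances, dtype=float)
    if ref.shape != (len(pairs),):
        raise ValueError("one reference distance per canonical pair required")
    if np.any(ref <= 0):
        raise ValueError("reference distances must be positive")
    r = pair_distances(geom)
    if np.any(r < 1e-12):
        raise ValueError("coincident atoms (zero internuclear distance)")
    return FeatureVector(values=ref / r, pair_order=pairs)


def featurize_ensemble(
    ensemble: list[Geometry], ref_distances: np.ndarray | None = None
) -> np.ndarray:
    """Feature matrix (n_geometries, n_pairs); reference defaults to ensemble means."""
    if ref_distances is None:
        ref_distances = ensemble_reference_distances(ensemble)
    return np.array([featurize(g, ref_distances).values for g in ensemble])
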