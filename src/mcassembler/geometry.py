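"""Rigid-body superposition and the three geometric predicates of assembly.

Three distance rules govern the assembly process:

* interface contact — CB atoms (CA for glycine) of two chains within 8 A;
* overlap — strictly more than 50% of the shorter chain's CA atoms within
  5 A of the other chain (assembly paths are discontinued on overlap);
* clash — two atoms from different chains within 1 A (about the size of a
  hydrogen atom).

Neighbour queries go through a KD-tree but are contractually identical to the
brute-force double loop (tested).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial import cKDTree

from .structio import ChainStructure

CONTACT_CUTOFF = 8.0   # A, CB-CB interface contact
OVERLAP_CUTOFF = 5.0   # A, CA-CA for the overlap predicate
OVERLAP_FRACTION = 0.5  # strict > ("over 50%")
CLASH_CUTOFF = 1.0     # A, strict <


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (column-vector convention)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise GeometryError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def _unchecked(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        """Construction without re-validation, for rotations produced by SVD."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "rotation", rotation)
        object.__setattr__(obj, "translation", translation)
        return obj

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


def superpose(fixed: np.ndarray, mobile: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid transform mapping ``mobile`` onto ``fixed``.

    SVD-based (Kabsch) superposition with reflection correction; at least
    three non-collinear points are required for the rotation to be defined.
    Returns the transform and the post-fit RMSD in Angstrom.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape:
        raise GeometryError(f"point count mismatch: {fixed.shape} vs {mobile.shape}")
    if fixed.ndim != 2 or fixed.shape[1] != 3:
        raise GeometryError("expected Nx3 coordinate arrays")
    n = fixed.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 points to superpose, got {n}")
    for pts, which in ((fixed, "fixed"), (mobile, "mobile")):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise GeometryError(f"{which} points are (nearly) collinear; rotation undefined")
    sup = SVDSuperimposer()
    sup.set(fixed, mobile)
    sup.run()
    rot, tran = sup.get_rotran()  # row-vector convention: mobile @ rot + tran
    return RigidTransform._unchecked(np.ascontiguousarray(rot.T), tran), float(sup.get_rms())


# below this pair-count the dense numpy distance matrix beats KD-tree construction
_BRUTE_FORCE_LIMIT = 250_000


def _pairs_within(a: np.ndarray, b: np.ndarray, r: float,
                  strict: bool) -> list[tuple[int, int]]:
    """Index pairs (i into a, j into b) with distance <= r (or < r if strict).

    Dense evaluation for small chains, KD-tree for large ones; both routes
    return exactly the brute-force double-loop answer.
    """
    if a.shape[0] * b.shape[0] <= _BRUTE_FORCE_LIMIT:
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        ii, jj = np.nonzero((d < r) if strict else (d <= r))
        return list(zip(ii.tolist(), jj.tolist()))
    ta, tb = cKDTree(a), cKDTree(b)
    out = []
    for i, js in enumerate(ta.query_ball_tree(tb, r)):
        for j in js:
            d = float(np.linalg.norm(a[i] - b[j]))
            if (d < r) if strict else (d <= r):
                out.append((i, j))
    return out


def min_dists(points: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Per-point minimum distance from ``points`` to the ``others`` set."""
    if points.shape[0] * others.shape[0] <= _BRUTE_FORCE_LIMIT:
        return np.linalg.norm(points[:, None, :] - others[None, :, :], axis=2).min(axis=1)
    d, _ = cKDTree(others).query(points)
    return d


def count_clashes(a: ChainStructure, b: ChainStructure) -> int:
    """Number of atom pairs (one from each chain) strictly within 1 A."""
    return len(_pairs_within(a.atom_coords, b.atom_coords, CLASH_CUTOFF, strict=True))


def is_overlap(a: ChainStructure, b: ChainStructure) -> bool:
    """True iff over half the shorter chain's CA atoms lie within 5 A of the other chain."""
    short, other = (a, b) if len(a) <= len(b) else (b, a)
    d = min_dists(short.ca_coords, other.ca_coords)
    return (d <= OVERLAP_CUTOFF).sum() > OVERLAP_FRACTION * len(short)


def interface_contacts(a: ChainStructure, b: ChainStructure,
                       cutoff: float = CONTACT_CUTOFF) -> list[tuple[int, int]]:
    """Residue-index pairs whose CB atoms (CA for glycine) are within ``cutoff``.

    Returned indices are the residue numbers of ``a`` and ``b`` respectively;
    swapping the arguments transposes the pairs.
    """
    pairs = _pairs_within(a.cb_coords, b.cb_coords, cutoff, strict=False)
    ia, ib = a.residue_indices, b.residue_indices
    return [(int(ia[i]), int(ib[j])) for i, j in pairs]
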