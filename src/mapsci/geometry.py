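"""Closed-form rigid-body superposition and distance primitives.

Coordinates are row vectors; a rigid transform maps a coordinate matrix
``B`` (n×3) to ``(B - e·t)·R`` where ``t`` is a 1×3 translation row,
``e`` the all-ones column and ``R`` a proper rotation acting on the
right.  All modules share this convention.

The optimal rotation between two matched, centered point sets is the
classic SVD (Kabsch) solution: with ``M = Bᵀ·A = U·Σ·Vᵀ`` the rotation
``R = U·W·Vᵀ`` with ``W = diag(1, 1, det(U·Vᵀ))`` maximizes
``trace(Aᵀ·B·R)`` over proper rotations; the determinant correction
excludes reflections when the best orthogonal map would be improper.
The optimal translation simply matches the two centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "optimal_rotation",
    "optimal_translation",
    "superpose",
    "rmsd",
]

_ORTHO_ATOL = 1e-6


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``coords -> (coords - t) @ R``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.array(self.rotation, dtype=float)
        t = np.array(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_ATOL):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0.0:
            raise ValueError("rotation is a reflection (det < 0)")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array (or a single triple)."""
        c = np.asarray(coords, dtype=float)
        return (c - self.translation) @ self.rotation

    def compose(self, later: "RigidTransform") -> "RigidTransform":
        """The single transform equivalent to applying ``self`` then ``later``."""
        R = self.rotation @ later.rotation
        t = self.translation + later.translation @ self.rotation.T
        return RigidTransform(R, t)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.translation @ self.rotation)

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def _as_points(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array")
    if X.shape[0] == 0:
        raise ValueError(f"{name} must contain at least one point")
    return X


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ``||A_c - B_c @ R||²`` over rotations.

    Both point sets are centered internally.  Degenerate inputs (all
    points coincident after centering) return the identity with a
    warning; rank-deficient covariances (collinear/coplanar sets) use
    the same determinant rule — the optimum may then be non-unique.
    """
    A = _as_points(A, "A")
    B = _as_points(B, "B")
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have equal row counts")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    M = Bc.T @ Ac
    if not np.any(np.abs(M) > 0.0):
        if A.shape[0] > 1:
            warnings.warn("degenerate point sets: rotation is undetermined, "
                          "returning identity", stacklevel=2)
        return np.eye(3)
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    W = np.diag([1.0, 1.0, d])
    return U @ W @ Vt


def optimal_translation(A: np.ndarray, B: np.ndarray,
                        rotation: np.ndarray) -> np.ndarray:
    """Translation t such that ``(B - t) @ R`` and ``A`` share a centroid.

    Closed form: ``t = centroid(B) - centroid(A) @ Rᵀ``.
    """
    A = _as_points(A, "A")
    B = _as_points(B, "B")
    R = np.asarray(rotation, dtype=float)
    return B.mean(axis=0) - A.mean(axis=0) @ R.T


def superpose(A: np.ndarray, B: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``B`` onto ``A``.

    Returns the transform and the residual sum of squared distances (Å²)
    between ``A`` and the transformed ``B``.  The residual never exceeds
    the identity-transform residual.
    """
    A = _as_points(A, "A")
    B = _as_points(B, "B")
    R = optimal_rotation(A, B)
    t = optimal_translation(A, B, R)
    tf = RigidTransform(R, t)
    diff = A - tf.apply(B)
    return tf, float(np.einsum("ij,ij->", diff, diff))


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square deviation between matched coordinate rows (Å)."""
    A = _as_points(A, "A")
    B = _as_points(B, "B")
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have equal row counts")
    diff = A - B
    return float(np.sqrt(np.einsum("ij,ij->", diff, diff) / A.shape[0]))
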