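"""Rotation-group numerics, superposition, and backbone frames.

Everything downstream — the rigid-body flow, the pair features, and the
docking metrics — is built on the primitives in this module: the SO(3)
exponential/logarithm maps, Haar-uniform rotation sampling, geodesic
interpolation between rotations, Kabsch superposition, and per-residue
backbone frames.

Conventions
-----------
* Rotations are 3x3 orthonormal matrices with determinant +1.
* Axis-angle vectors are ``angle * unit_axis`` with angle in radians,
  principal branch ``|omega| in [0, pi]``.
* The rotation geodesic is evaluated in the right-translated form
  ``R_t = R1 @ exp((1 - t) * log(R1.T @ R0))`` so that ``t=0`` gives ``R0``
  and ``t=1`` gives ``R1``.
* All operations are deterministic given their inputs (and the supplied
  random generator, where one is taken).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: below this rotation angle the exp/log maps switch to their series limits
SMALL_ANGLE = 1e-7

#: tolerance used when validating rotation matrices
ORTHONORMAL_TOL = 1e-8

__all__ = [
    "RigidTransform",
    "BackboneFrameSet",
    "is_rotation_matrix",
    "check_rotation_matrix",
    "so3_exp",
    "so3_log",
    "sample_uniform_rotation",
    "geodesic_rotation",
    "kabsch_align",
    "backbone_frames",
]


def is_rotation_matrix(R: np.ndarray, tol: float = 1e-6) -> bool:
    """Return True if ``R`` is orthonormal with determinant +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        return False
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and abs(np.linalg.det(R) - 1.0) <= tol
    )


def check_rotation_matrix(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Validate and return ``R`` as a float array; raise ValueError otherwise."""
    R = np.asarray(R, dtype=float)
    if not is_rotation_matrix(R, tol=tol):
        raise ValueError("expected an orthonormal 3x3 matrix with det +1")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> rotation @ x + translation`` (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("RigidTransform needs a 3x3 rotation and a 3-vector")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (..., 3) array of points."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class BackboneFrameSet:
    """Per-residue orthonormal frames with CA origins.

    ``rotations`` is (L, 3, 3) with frame axes as *columns* (a local vector v
    maps to the global vector ``rotations[i] @ v``), ``origins`` is (L, 3) and
    equals the CA positions, ``valid`` is an (L,) boolean mask.
    """

    rotations: np.ndarray
    origins: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.valid)


def _hat(omega: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix of a 3-vector (the so(3) hat map)."""
    wx, wy, wz = omega
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def so3_exp(axis_angle: np.ndarray) -> np.ndarray:
    """Exponential map so(3) -> SO(3) via the Rodrigues formula.

    ``axis_angle`` is ``angle * unit_axis``; the zero vector maps to the
    identity through the series limit.
    """
    omega = np.asarray(axis_angle, dtype=float)
    if omega.shape != (3,) or not np.all(np.isfinite(omega)):
        raise ValueError("axis_angle must be a finite 3-vector")
    theta = np.linalg.norm(omega)
    K = _hat(omega)
    if theta < SMALL_ANGLE:
        # second-order series; exact to O(theta^3)
        return np.eye(3) + K + 0.5 * (K @ K)
    a = np.sin(theta) / theta
    b = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + a * K + b * (K @ K)


def so3_log(R: np.ndarray) -> np.ndarray:
    """Logarithm map SO(3) -> so(3), principal branch ``|omega| <= pi``.

    Rotations within ~1e-6 of a half-turn are resolved through the
    eigenvector of the symmetric part, which stays well conditioned where
    the sine-based formula loses all precision.
    """
    R = check_rotation_matrix(R)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < SMALL_ANGLE:
        # series limit: log R ~ (R - R.T)/2 for small angles
        A = 0.5 * (R - R.T)
        return np.array([A[2, 1], A[0, 2], A[1, 0]])
    if np.pi - theta < 1e-6:
        # near pi: axis from the dominant eigenvector of (R + I)/2
        S = 0.5 * (R + np.eye(3))
        axis = S[:, np.argmax(np.diag(S))]
        axis = axis / np.linalg.norm(axis)
        # fix the sign deterministically: first nonzero component positive
        for c in axis:
            if abs(c) > 1e-12:
                if c < 0:
                    axis = -axis
                break
        return theta * axis
    A = 0.5 * (R - R.T) / np.sin(theta)
    return theta * np.array([A[2, 1], A[0, 2], A[1, 0]])


def sample_uniform_rotation(rng: np.random.Generator) -> np.ndarray:
    """Draw a Haar-uniform rotation from SO(3).

    A unit quaternion is obtained by normalizing a 4D standard Gaussian,
    which is exactly uniform on S^3 and hence Haar on SO(3).
    """
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def geodesic_rotation(R0: np.ndarray, R1: np.ndarray, t: float) -> np.ndarray:
    """Point at parameter ``t`` on the SO(3) geodesic from ``R0`` to ``R1``.

    Evaluated as ``R1 @ exp((1 - t) * log(R1.T @ R0))``; endpoints are exact.
    When ``R1.T @ R0`` is a half-turn the minimizing geodesic is not unique;
    the principal log branch is used deterministically and a warning emitted.
    """
    R0 = check_rotation_matrix(R0)
    R1 = check_rotation_matrix(R1)
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    rel = R1.T @ R0
    omega = so3_log(rel)
    if np.pi - np.linalg.norm(omega) < 1e-6:
        warnings.warn(
            "geodesic between rotations differing by a half-turn is not "
            "unique; using the principal branch",
            stacklevel=2,
        )
    return R1 @ so3_exp((1.0 - t) * omega)


def kabsch_align(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform (reflection excluded) minimizing the
    RMSD of the masked points and the post-alignment RMSD itself.

    Parameters
    ----------
    mobile, reference : (N, 3) arrays with matching point counts.
    mask : optional (N,) boolean selecting the points entering the fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (N, 3) arrays")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(mobile),):
            raise ValueError("mask length must match the point count")
        mobile_sel = mobile[mask]
        reference_sel = reference[mask]
    else:
        mobile_sel, reference_sel = mobile, reference
    n = len(mobile_sel)
    if n < 3:
        raise ValueError(f"need at least 3 points for superposition, got {n}")

    mob_c = mobile_sel.mean(axis=0)
    ref_c = reference_sel.mean(axis=0)
    P = mobile_sel - mob_c
    Q = reference_sel - ref_c
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(P, tol=1e-8) < 2 or np.linalg.matrix_rank(Q, tol=1e-8) < 2:
        raise ValueError("points are collinear; superposition is degenerate")

    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    translation = ref_c - R @ mob_c
    transform = RigidTransform(R, translation)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mobile_sel) - reference_sel) ** 2, axis=1))))
    return transform, rmsd


def backbone_frames(
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    atom_valid: np.ndarray | None = None,
) -> BackboneFrameSet:
    """Gram-Schmidt backbone frames from N, CA, C coordinates.

    ``e1`` points along CA->C, ``e2`` is the CA->N direction orthogonalized
    against ``e1``, ``e3 = e1 x e2``; the origin is the CA position.
    Residues with a missing or degenerate (collinear) backbone are masked
    invalid rather than raising.

    Parameters
    ----------
    n, ca, c : (L, 3) coordinate arrays.
    atom_valid : optional (L,) boolean; False rows are masked invalid.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    L = len(ca)
    rotations = np.tile(np.eye(3), (L, 1, 1))
    valid = np.ones(L, dtype=bool) if atom_valid is None else np.asarray(atom_valid, dtype=bool).copy()
    for i in range(L):
        if not valid[i]:
            continue
        v1 = c[i] - ca[i]
        v2 = n[i] - ca[i]
        n1 = np.linalg.norm(v1)
        if n1 < 1e-6:
            valid[i] = False
            continue
        e1 = v1 / n1
        u2 = v2 - (v2 @ e1) * e1
        n2 = np.linalg.norm(u2)
        if n2 < 1e-6:
            logger.warning("degenerate backbone geometry at residue %d; frame masked", i)
            valid[i] = False
            continue
        e2 = u2 / n2
        e3 = np.cross(e1, e2)
        rotations[i] = np.stack([e1, e2, e3], axis=1)
    return BackboneFrameSet(rotations=rotations, origins=ca.copy(), valid=valid)
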