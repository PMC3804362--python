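"""Rigid (rotation + translation) organ-to-organ registration.

Normalization step of the pipeline: every subject's organ is rigidly
aligned to the same reference subject so that positional and rotational
differences carry no weight in the shape statistics.  Scale is *not*
estimated — organ size (hypertrophy/atrophy, splenomegaly) is diagnostic
signal and must survive normalization.

The solver is iterative closest point (ICP) on the surface vertices,
initialized by centroid alignment plus principal-axes orientation (all
four proper-rotation axis-sign combinations are tried and the identity
attitude is always included as a candidate).  Rotations are constrained to
det = +1 throughout; a mirrored input therefore cannot be matched and is
reported as non-converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .surface import Surface
from .volume import LabelVolume


@dataclass
class RigidTransform:
    """Proper rigid motion x -> rotation @ x + translation (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = field(default=float("nan"), compare=False)
    converged: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflections are not representable (det must be +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def rotation_angle(self) -> float:
        """Rotation angle in degrees (0 for the identity)."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist(),
                "residual": self.residual, "converged": self.converged}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]),
                   residual=d.get("residual", float("nan")), converged=d.get("converged", True))


def apply_transform(surface: Surface, t: RigidTransform) -> Surface:
    """Map a surface through a rigid transform; faces are unchanged."""
    return Surface(t.apply(surface.vertices), surface.faces.copy(),
                   organ=surface.organ, subject_id=surface.subject_id)


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares proper rotation + translation mapping src onto dst."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    h = (src - mu_s).T @ (dst - mu_d)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mu_d - r @ mu_s


def _principal_axes(points: np.ndarray) -> np.ndarray:
    cov = np.cov((points - points.mean(axis=0)).T)
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1]  # descending variance
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    return axes


def _as_points(obj: Surface | LabelVolume) -> np.ndarray:
    if isinstance(obj, LabelVolume):
        from .surface import extract_surface

        obj = extract_surface(obj)
    return obj.vertices


def register_rigid(moving: Surface | LabelVolume, reference: Surface | LabelVolume,
                   max_iterations: int = 100, tolerance: float = 1e-10,
                   converged_fraction: float = 0.02) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    Returns the transform minimizing the mean squared nearest-neighbour
    surface distance.  ``residual`` holds the final RMS distance (mm) and
    ``converged`` is False when that residual exceeds ``converged_fraction``
    of the reference bounding-box diagonal — the signature of an input that
    rigid motion cannot align, e.g. a mirrored organ.

    Raises ``ValueError`` on degenerate (rank-deficient) inputs.
    """
    mov = _as_points(moving)
    ref = _as_points(reference)
    if len(mov) < 3 or len(ref) < 3:
        raise ValueError("registration needs at least 3 points per input")
    for pts in (mov, ref):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] <= 1e-9 * max(s[0], 1.0):
            raise ValueError("degenerate input: points are collinear")

    tree = cKDTree(ref)
    mu_m, mu_r = mov.mean(axis=0), ref.mean(axis=0)
    axes_m, axes_r = _principal_axes(mov), _principal_axes(ref)

    inits = [RigidTransform(np.eye(3), mu_r - mu_m)]
    for flip in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        r0 = axes_r @ np.diag(flip) @ axes_m.T
        inits.append(RigidTransform(r0, mu_r - r0 @ mu_m))

    best: RigidTransform | None = None
    for t in inits:
        rms_prev = np.inf
        for _ in range(max_iterations):
            cur = t.apply(mov)
            d, idx = tree.query(cur)
            rms = float(np.sqrt(np.mean(d ** 2)))
            if rms_prev - rms < tolerance * (1.0 + rms_prev):
                break
            rms_prev = rms
            r, tr = _kabsch(mov, ref[idx])
            t = RigidTransform(r, tr)
        cur = t.apply(mov)
        d, _ = tree.query(cur)
        t.residual = float(np.sqrt(np.mean(d ** 2)))
        if best is None or t.residual < best.residual:
            best = t

    diag = float(np.linalg.norm(ref.max(axis=0) - ref.min(axis=0)))
    best.converged = best.residual <= converged_fraction * diag
    return best
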