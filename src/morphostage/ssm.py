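"""Statistical shape models (point distribution models) of liver and spleen.

A shape is a flat coordinate vector over corresponded vertices,

    x = [x1, y1, z1, ..., xV, yV, zV]          (single organ, length 3V)
    x = [x_liver, x_spleen]                     (joint model, length 6V)

With N training shapes, the model is the eigen-decomposition of the
sample covariance S = (1/N) sum_i (x_i - m)(x_i - m)^T around the mean
m = (1/N) sum_i x_i.  The 1/N normalization (rather than 1/(N-1)) follows
the point-distribution-model convention; it scales eigenvalues only.  Any
shape is encoded by mode coefficients b_j = v_j^T (x - m) and decoded as
x = m + sum_j b_j v_j.

The decomposition is computed through the N x N Gram matrix (thin SVD of
the centered data), so the 3V x 3V covariance is never materialized; at
most N - 1 modes carry variance.

The module follows the model/results idiom: ``StatisticalShapeModel``
holds the training data, ``fit()`` returns a ``ShapeModelResults`` with
the estimates and the project/reconstruct machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .surface import Surface

LAYOUTS = ("liver", "spleen", "joint")


@dataclass
class ShapeVector:
    """Flattened corresponded-vertex coordinates of one subject.

    ``layout`` is "liver", "spleen" (length 3V) or "joint" (liver block
    before spleen block, length 6V).
    """

    values: np.ndarray
    layout: str = "liver"
    subject_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        block = 6 if self.layout == "joint" else 3
        if len(self.values) == 0 or len(self.values) % block:
            raise ValueError(f"{self.layout} vector length must be a positive multiple of {block}")

    @property
    def n_vertices(self) -> int:
        return len(self.values) // (6 if self.layout == "joint" else 3)


def assemble_shape_vector(*surfaces: Surface, subject_id: str = "") -> ShapeVector:
    """Flatten one corresponded surface (or a liver + spleen pair) into a
    shape vector.

    The joint form requires exactly one liver and one spleen with equal
    vertex counts; the liver block always precedes the spleen block.
    """
    if len(surfaces) == 1:
        s = surfaces[0]
        layout = s.organ if s.organ in ("liver", "spleen") else "liver"
        return ShapeVector(s.vertices.ravel(), layout, subject_id=subject_id or s.subject_id)
    if len(surfaces) == 2:
        organs = {s.organ for s in surfaces}
        if organs != {"liver", "spleen"}:
            raise ValueError("joint shape vector requires one liver and one spleen")
        liver = next(s for s in surfaces if s.organ == "liver")
        spleen = next(s for s in surfaces if s.organ == "spleen")
        if liver.n_vertices != spleen.n_vertices:
            raise ValueError("mismatched vertex counts between liver and spleen")
        return ShapeVector(np.concatenate([liver.vertices.ravel(), spleen.vertices.ravel()]),
                           "joint", subject_id=subject_id or liver.subject_id)
    raise ValueError("assemble_shape_vector takes one or two surfaces")


def shape_vector_to_surfaces(vec: ShapeVector, faces: np.ndarray) -> tuple[Surface, ...]:
    """Inverse of :func:`assemble_shape_vector` given the reference faces."""
    if vec.layout == "joint":
        half = len(vec.values) // 2
        liver = vec.values[:half].reshape(-1, 3)
        spleen = vec.values[half:].reshape(-1, 3)
        return (Surface(liver, faces, organ="liver", subject_id=vec.subject_id),
                Surface(spleen, faces, organ="spleen", subject_id=vec.subject_id))
    return (Surface(vec.values.reshape(-1, 3), faces, organ=vec.layout,
                    subject_id=vec.subject_id),)


@dataclass
class ModeCoefficients:
    """Per-mode weights b_j of one subject in one fitted shape model."""

    values: np.ndarray
    model_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


class StatisticalShapeModel:
    """PCA shape model over a training set of corresponded shape vectors.

    Parameters
    ----------
    shapes : (N, D) array or sequence of ShapeVector
        Training shapes, one row per subject, all in the same layout.
    layout : str
        "liver", "spleen" or "joint"; inferred from ShapeVector inputs.
    subject_ids, reference_id : bookkeeping carried into the results.
    """

    def __init__(self, shapes, layout: str | None = None,
                 subject_ids: list[str] | None = None, reference_id: str = ""):
        if len(shapes) and isinstance(shapes[0], ShapeVector):
            layouts = {s.layout for s in shapes}
            if len(layouts) != 1:
                raise ValueError(f"mixed layouts in training set: {layouts}")
            layout = layouts.pop()
            subject_ids = subject_ids or [s.subject_id for s in shapes]
            shapes = np.stack([s.values for s in shapes])
        data = np.asarray(shapes, dtype=float)
        if data.ndim != 2:
            raise ValueError("shapes must form an (N, D) matrix")
        if data.shape[0] < 2:
            raise ValueError("at least 2 training shapes are required")
        self.data = data
        self.layout = layout or "liver"
        self.subject_ids = list(subject_ids) if subject_ids else [str(i) for i in range(len(data))]
        self.reference_id = reference_id

    def fit(self, min_eigenvalue_ratio: float = 1e-10) -> "ShapeModelResults":
        """Fit mean and eigenshapes via the dual (Gram / thin-SVD) route.

        Modes with eigenvalue below ``min_eigenvalue_ratio`` times the
        leading eigenvalue are discarded as numerical noise.
        """
        n = len(self.data)
        mean = self.data.mean(axis=0)
        centered = self.data - mean
        # thin SVD of (1/sqrt(N)) X_c gives eigenpairs of S = (1/N) X_c^T X_c
        u, s, vt = np.linalg.svd(centered / np.sqrt(n), full_matrices=False)
        eigenvalues = s ** 2
        keep = min(n - 1, len(eigenvalues))
        eigenvalues = eigenvalues[:keep]
        eigenshapes = vt[:keep]
        if eigenvalues[0] > 0:
            nz = eigenvalues >= min_eigenvalue_ratio * eigenvalues[0]
            eigenvalues, eigenshapes = eigenvalues[nz], eigenshapes[nz]
        # deterministic sign: the entry of largest magnitude is positive
        for j in range(len(eigenshapes)):
            k = int(np.argmax(np.abs(eigenshapes[j])))
            if eigenshapes[j, k] < 0:
                eigenshapes[j] *= -1
        return ShapeModelResults(mean=mean, eigenshapes=eigenshapes, eigenvalues=eigenvalues,
                                 n_train=n, layout=self.layout, reference_id=self.reference_id,
                                 subject_ids=self.subject_ids)


@dataclass
class ShapeModelResults:
    """Fitted shape model: mean, eigenshapes and the coefficient algebra."""

    mean: np.ndarray
    eigenshapes: np.ndarray  # (k, D), orthonormal rows, variance-ordered
    eigenvalues: np.ndarray  # (k,), non-increasing, 1/N-normalized variances
    n_train: int
    layout: str = "liver"
    reference_id: str = ""
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def project(self, x: ShapeVector | np.ndarray, n_modes: int | None = None) -> ModeCoefficients:
        """Mode coefficients b_j = v_j^T (x - m) for j = 1..n_modes."""
        sid = ""
        if isinstance(x, ShapeVector):
            if x.layout != self.layout:
                raise ValueError(f"layout mismatch: model {self.layout!r}, shape {x.layout!r}")
            sid = x.subject_id
            x = x.values
        x = np.asarray(x, dtype=float).ravel()
        if x.shape != self.mean.shape:
            raise ValueError("shape vector length does not match the model")
        k = self.n_modes if n_modes is None else int(n_modes)
        if not 1 <= k <= self.n_modes:
            raise ValueError(f"n_modes must be in [1, {self.n_modes}]")
        return ModeCoefficients(self.eigenshapes[:k] @ (x - self.mean),
                                model_id=self.layout, subject_id=sid)

    def reconstruct(self, b: ModeCoefficients | np.ndarray) -> ShapeVector:
        """Shape x = m + sum_j b_j v_j."""
        sid = ""
        if isinstance(b, ModeCoefficients):
            sid = b.subject_id
            b = b.values
        b = np.asarray(b, dtype=float).ravel()
        if len(b) > self.n_modes:
            raise ValueError("more coefficients than stored modes")
        return ShapeVector(self.mean + b @ self.eigenshapes[:len(b)], self.layout, subject_id=sid)

    def coefficient_matrix(self, shapes, n_modes: int | None = None) -> np.ndarray:
        """(N, k) matrix of coefficients for a stack of shapes."""
        if len(shapes) and isinstance(shapes[0], ShapeVector):
            shapes = np.stack([s.values for s in shapes])
        shapes = np.asarray(shapes, dtype=float)
        k = self.n_modes if n_modes is None else int(n_modes)
        return (shapes - self.mean) @ self.eigenshapes[:k].T

    def avcr(self, k: int) -> float:
        """Accumulated variance contribution rate of the first k modes."""
        if not 1 <= k <= self.n_modes:
            raise ValueError(f"k must be in [1, {self.n_modes}]")
        total = self.eigenvalues.sum()
        if total <= 0:
            raise ValueError("AVCR undefined: all eigenvalues are zero")
        return float(self.eigenvalues[:k].sum() / total)

    def summary(self) -> str:
        lines = [
            f"Statistical shape model ({self.layout}), N = {self.n_train} training shapes",
            f"reference subject: {self.reference_id or '-'}; "
            f"shape vector length {len(self.mean)}; {self.n_modes} retained modes",
            f"{'mode':>4} {'eigenvalue':>14} {'VCR':>8} {'AVCR':>8}",
        ]
        total = self.eigenvalues.sum()
        acc = 0.0
        for j, lam in enumerate(self.eigenvalues, start=1):
            vcr = lam / total if total > 0 else 0.0
            acc += vcr
            lines.append(f"{j:>4} {lam:>14.6g} {vcr:>8.4f} {acc:>8.4f}")
        return "\n".join(lines)

    # -- serialization -------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the model as a single .npz archive."""
        np.savez_compressed(
            Path(path), mean=self.mean, eigenshapes=self.eigenshapes,
            eigenvalues=self.eigenvalues, n_train=self.n_train, layout=self.layout,
            reference_id=self.reference_id, subject_ids=np.asarray(self.subject_ids, dtype=object))

    @classmethod
    def load(cls, path: str | Path) -> "ShapeModelResults":
        with np.load(Path(path), allow_pickle=True) as z:
            return cls(mean=z["mean"], eigenshapes=z["eigenshapes"], eigenvalues=z["eigenvalues"],
                       n_train=int(z["n_train"]), layout=str(z["layout"]),
                       reference_id=str(z["reference_id"]), subject_ids=list(z["subject_ids"]))


def fit_ssm(training, layout: str | None = None, reference_id: str = "") -> ShapeModelResults:
    """Convenience wrapper: fit a shape model from a list of shape vectors."""
    return StatisticalShapeModel(training, layout=layout, reference_id=reference_id).fit()
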