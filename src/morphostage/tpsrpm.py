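"""Non-rigid point matching by TPS-RPM (robust point matching).

Establishes one-to-one vertex correspondence between a subject surface and
the reference surface by alternating softassign correspondence updates
with thin-plate-spline (TPS) refits under a deterministic-annealing
temperature schedule.  At high temperature the match is fuzzy and the warp
nearly affine; as the temperature anneals down the assignment matrix
hardens toward a permutation and the warp localizes.

The matcher is deterministic: there is no randomness given the inputs and
the schedule.  Point sets are normalized internally (reference centroid /
RMS-radius scale) so the default temperatures are dimensionless; the
returned warp acts in physical coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .surface import Surface

log = logging.getLogger(__name__)


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    # 3-D biharmonic spline kernel, sign chosen so the bending penalty
    # w^T K w is positive semi-definite on the side-condition subspace
    return -r


@dataclass
class TPSWarp:
    """Thin-plate-spline deformation f(x) = A[x;1] + sum_k w_k phi(|x - c_k|)."""

    affine: np.ndarray  # (3, 4), last column is the translation
    kernel_weights: np.ndarray  # (K, 3)
    control_points: np.ndarray  # (K, 3)
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.kernel_weights = np.asarray(self.kernel_weights, dtype=float)
        self.control_points = np.asarray(self.control_points, dtype=float)
        if self.affine.shape != (3, 4):
            raise ValueError("affine must be 3x4")
        if self.kernel_weights.shape != self.control_points.shape:
            raise ValueError("kernel_weights and control_points must both be (K, 3)")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    @classmethod
    def identity(cls) -> "TPSWarp":
        return cls(np.hstack([np.eye(3), np.zeros((3, 1))]),
                   np.zeros((0, 3)), np.zeros((0, 3)))

    def side_condition_residual(self) -> float:
        """Max violation of the TPS side conditions P_c^T w = 0."""
        if len(self.control_points) == 0:
            return 0.0
        p = np.hstack([self.control_points, np.ones((len(self.control_points), 1))])
        return float(np.abs(p.T @ self.kernel_weights).max())

    def transform(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        out = points @ self.affine[:, :3].T + self.affine[:, 3]
        if len(self.control_points):
            u = _tps_kernel(cdist(points, self.control_points))
            out = out + u @ self.kernel_weights
        return out


def tps_warp_points(warp: TPSWarp, points: np.ndarray) -> np.ndarray:
    """Apply a TPS warp to an (n, 3) point array."""
    return warp.transform(points)


def fit_tps(data_points: np.ndarray, targets: np.ndarray, control_points: np.ndarray | None = None,
            regularization: float = 0.0, affine_regularization: float = 0.0) -> TPSWarp:
    """Least-squares TPS fit mapping data_points toward targets.

    Minimizes ``|f(data) - targets|^2 + regularization * bending(f) +
    affine_regularization * |affine - identity|^2`` over warps with kernel
    terms at ``control_points`` (default: the data points themselves),
    subject to the standard side conditions that make the kernel weights
    orthogonal to the affine basis.  The affine anchor keeps the map from
    collapsing toward the target barycentre when the targets are fuzzy
    (softassign at high temperature).  With both regularizations ``-> 0``
    and control = data the fit interpolates the targets exactly.
    """
    x = np.asarray(data_points, dtype=float)
    y = np.asarray(targets, dtype=float)
    c = x if control_points is None else np.asarray(control_points, dtype=float)
    n, k = len(x), len(c)
    if y.shape != x.shape:
        raise ValueError("data_points and targets must have identical shapes")
    p_c = np.hstack([c, np.ones((k, 1))])  # (K, 4)
    q, _ = np.linalg.qr(p_c, mode="complete")
    z = q[:, 4:]  # (K, K-4) basis of the side-condition null space
    phi_xc = _tps_kernel(cdist(x, c))
    phi_cc = _tps_kernel(cdist(c, c))
    p_x = np.hstack([x, np.ones((n, 1))])
    design = np.hstack([phi_xc @ z, p_x])  # unknowns: (u, affine^T)
    penalty = np.zeros((design.shape[1],) * 2)
    m = z.shape[1]
    penalty[:m, :m] = z.T @ phi_cc @ z
    gram = design.T @ design + regularization * penalty
    rhs = design.T @ y
    if affine_regularization > 0:
        gram[m:, m:] += affine_regularization * np.eye(4)
        rhs[m:m + 3] += affine_regularization * np.eye(3)  # anchor A at identity, t at 0
    gram += 1e-12 * np.trace(gram) / len(gram) * np.eye(len(gram))
    theta = np.linalg.solve(gram, rhs)
    w = z @ theta[:m]
    affine = theta[m:].T  # rows [A | t]
    return TPSWarp(affine, w, c, regularization=regularization)


@dataclass
class Correspondence:
    """Hard one-to-one assignment from reference vertex index to subject index."""

    mapping: np.ndarray  # (V,) subject index for each reference vertex
    outlier_mask: np.ndarray  # (V,) True where unmatched
    final_temperature: float
    residual: float = float("nan")  # mean squared warped-to-matched distance (mm^2)
    converged: bool = True

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=np.int64)
        self.outlier_mask = np.asarray(self.outlier_mask, dtype=bool)
        if self.mapping.shape != self.outlier_mask.shape:
            raise ValueError("mapping and outlier_mask must have equal length")
        used = self.mapping[~self.outlier_mask]
        if len(np.unique(used)) != len(used):
            raise ValueError("correspondence reuses a subject index")

    @property
    def is_complete(self) -> bool:
        return not self.outlier_mask.any()

    @classmethod
    def identity(cls, n: int) -> "Correspondence":
        return cls(np.arange(n), np.zeros(n, dtype=bool), 0.0, residual=0.0)

    def to_dict(self) -> dict:
        return {"mapping": self.mapping.tolist(), "outliers": np.flatnonzero(self.outlier_mask).tolist(),
                "final_temperature": self.final_temperature, "residual": self.residual,
                "converged": self.converged}


@dataclass
class AnnealingSchedule:
    """Deterministic-annealing parameters (dimensionless: unit-RMS coordinates).

    t_init : starting temperature; 0.5 corresponds to a fuzziness radius of
        the organ half-scale.  t_final defaults to the squared mean
        nearest-neighbour spacing of the normalized reference, the scale at
        which neighbouring vertices become distinguishable.
    decay : geometric factor applied to the temperature per outer step.
    inner_iterations : softassign/TPS alternations per temperature.
    n_control : TPS control points (farthest-point subsample of the reference).
    lambda_scale : TPS bending regularization is lambda_scale * N * T.
    """

    t_init: float = 0.1
    t_final: float | None = None
    decay: float = 0.93
    inner_iterations: int = 2
    n_control: int = 150
    lambda_scale: float = 0.01
    affine_lambda_scale: float = 0.1  # identity anchor on the affine part, also ~ N * T
    sinkhorn_iterations: int = 10
    max_outer: int = 200
    track_energy: bool = False  # record the free energy each alternation (diagnostic)


def _farthest_point_indices(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point sampling, seeded at index 0."""
    n = len(points)
    if k >= n:
        return np.arange(n)
    chosen = [0]
    d = np.linalg.norm(points - points[0], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(sorted(chosen))


def _greedy_assignment(m: np.ndarray) -> np.ndarray:
    """Conflict-free row-argmax: rows claimed in order of confidence,
    ties broken by smaller subject (column) index."""
    n = m.shape[0]
    order = np.argsort(-m.max(axis=1), kind="stable")
    taken = np.zeros(m.shape[1], dtype=bool)
    mapping = np.full(n, -1, dtype=np.int64)
    for i in order:
        row = np.where(taken, -np.inf, m[i])
        j = int(np.argmax(row))  # argmax returns the first (smallest) index on ties
        mapping[i] = j
        taken[j] = True
    return mapping


def match_tps_rpm(subject: Surface, reference: Surface,
                  schedule: AnnealingSchedule | None = None) -> tuple[Correspondence, TPSWarp]:
    """Match reference vertices to subject vertices by TPS-RPM.

    Both surfaces must carry the same (standardized) vertex count.  Returns
    the hard correspondence extracted from the final softassign matrix and
    the final TPS warp (in physical coordinates) that carries the reference
    onto the subject.  ``converged`` is False when the annealing loop was
    cut off by ``max_outer``.
    """
    schedule = schedule or AnnealingSchedule()
    x_phys = reference.vertices
    y_phys = subject.vertices
    if len(x_phys) != len(y_phys):
        raise ValueError("surfaces must be standardized to the same vertex count")
    n = len(x_phys)

    mu_x, mu_y = x_phys.mean(axis=0), y_phys.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((x_phys - mu_x) ** 2, axis=1))))
    x = (x_phys - mu_x) / scale
    y = (y_phys - mu_y) / scale

    t_final = schedule.t_final
    if t_final is None:
        nn = cKDTree(x).query(x, k=2)[0][:, 1]
        t_final = float(np.mean(nn) ** 2)
    ctrl_idx = _farthest_point_indices(x, schedule.n_control)
    ctrl = x[ctrl_idx]

    warp = TPSWarp.identity()
    temperature = schedule.t_init
    m = np.full((n, n), 1.0 / n)
    energies: list[tuple[int, float]] = []  # (outer index, free energy)
    outer = 0
    converged = True
    while temperature > t_final:
        if outer >= schedule.max_outer:
            converged = False
            log.warning("TPS-RPM hit max_outer=%d before reaching final temperature",
                        schedule.max_outer)
            break
        lam = schedule.lambda_scale * n * temperature
        lam_affine = schedule.affine_lambda_scale * n * temperature
        for _ in range(schedule.inner_iterations):
            warped = warp.transform(x)
            d2 = cdist(warped, y, "sqeuclidean")
            m = np.exp(-(d2 - d2.min(axis=1, keepdims=True)) / (2.0 * temperature))
            m += 1e-300
            for _ in range(schedule.sinkhorn_iterations):
                m /= m.sum(axis=0, keepdims=True)
                m /= m.sum(axis=1, keepdims=True)
            targets = (m @ y) / m.sum(axis=1, keepdims=True)
            warp = fit_tps(x, targets, control_points=ctrl, regularization=lam,
                           affine_regularization=lam_affine)
            if schedule.track_energy:
                energies.append((outer, _free_energy(warp, x, y, m, temperature,
                                                     lam, lam_affine)))
        temperature *= schedule.decay
        outer += 1

    mapping = _greedy_assignment(m)
    # final polish: refit the warp to the hard targets at the final
    # temperature's regularization, so the reported residual reflects the
    # returned correspondence (identical inputs -> identity warp, ~0)
    warp = fit_tps(x, y[mapping], control_points=ctrl,
                   regularization=schedule.lambda_scale * n * t_final)
    warped = warp.transform(x)
    residual_norm = float(np.mean(np.sum((warped - y[mapping]) ** 2, axis=1)))
    corr = Correspondence(mapping, np.zeros(n, dtype=bool), final_temperature=temperature,
                          residual=residual_norm * scale ** 2, converged=converged)
    corr.energies = energies  # per-iteration free energies, for diagnostics

    # map the warp back to physical coordinates
    a = warp.affine[:, :3]
    b = warp.affine[:, 3]
    affine_phys = np.hstack([a, (scale * b + mu_y - a @ mu_x)[:, None]])
    warp_phys = TPSWarp(affine_phys, warp.kernel_weights,
                        mu_x + scale * warp.control_points, regularization=warp.regularization)
    return corr, warp_phys


def _free_energy(warp: TPSWarp, x: np.ndarray, y: np.ndarray, m: np.ndarray,
                 temperature: float, lam: float, lam_affine: float) -> float:
    """Deterministic-annealing free energy at the current (warp, assignment).

    The softassign update is the exact minimiser of this functional over
    doubly-stochastic assignments (the Gaussian affinity exp(-d^2 / 2T)
    corresponds to an entropy weight of 2T), and the regularized TPS fit
    is the exact minimiser over warps, so each alternation at fixed
    temperature is coordinate descent on this quantity.
    """
    d2 = cdist(warp.transform(x), y, "sqeuclidean")
    entropy = float(np.sum(m * np.log(np.maximum(m, 1e-300))))
    bending = float(np.einsum("kd,kl,ld->", warp.kernel_weights,
                              _tps_kernel(cdist(warp.control_points, warp.control_points)),
                              warp.kernel_weights))
    affine_dev = float(np.sum((warp.affine - np.hstack([np.eye(3), np.zeros((3, 1))])) ** 2))
    return (float(np.sum(m * d2)) + 2.0 * temperature * entropy
            + lam * bending + lam_affine * affine_dev)


def reorder_by_correspondence(subject: Surface, corr: Correspondence) -> Surface:
    """Permute subject vertices into the reference vertex ordering.

    After reordering, vertex ``i`` of the result corresponds anatomically
    to reference vertex ``i``; faces are re-indexed consistently so the
    geometry is unchanged.
    """
    if not corr.is_complete:
        raise ValueError("correspondence has outliers; imputation is not enabled")
    if len(corr.mapping) != subject.n_vertices:
        raise ValueError("correspondence length does not match subject vertex count")
    inverse = np.empty_like(corr.mapping)
    inverse[corr.mapping] = np.arange(len(corr.mapping))
    return Surface(subject.vertices[corr.mapping], inverse[subject.faces],
                   organ=subject.organ, subject_id=subject.subject_id)
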