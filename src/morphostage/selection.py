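"""Supervised selection of diagnostically effective shape modes.

Two rankings are combined.  The variance route keeps the smallest prefix
of modes whose accumulated variance contribution rate (AVCR) reaches a
threshold.  The label route ranks modes by the uncentered absolute cosine
between the per-subject coefficient vector of the mode and the clinical
label vector (normal = 0, abnormal = 1),

    correlation_i = |r^T b_i| / sqrt((r^T r)(b_i^T b_i)),

and keeps the top-k (default 4).  The selected modes are the product set
(intersection) of the two, ordered by correlation; a final count (default
1 per model) keeps only the strongest.  Note the deliberate absence of
mean-centering: this is the raw cosine, not Pearson correlation (a
centered variant is available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ssm import ShapeModelResults

log = logging.getLogger(__name__)


@dataclass
class LabelVector:
    """Per-subject clinical labels in fixed subject order."""

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) == 0:
            raise ValueError("label vector is empty")
        if not np.any(self.values):
            raise ValueError("label vector must contain at least one nonzero entry")


@dataclass
class ModeSelection:
    """Outcome of combined mode selection (1-based mode indices)."""

    avcr_set: tuple[int, ...]
    corr_set: tuple[int, ...]
    selected: tuple[int, ...]  # ordered by correlation, descending
    correlations: dict[int, float]
    fallback_used: bool = False


def mode_label_correlation(coeffs_for_mode: np.ndarray, labels: LabelVector | np.ndarray,
                           centered: bool = False) -> float:
    """Uncentered absolute cosine between one mode's coefficients and the labels.

    ``centered=True`` switches to the Pearson (mean-centered) variant.
    """
    b = np.asarray(coeffs_for_mode, dtype=float).ravel()
    r = labels.values if isinstance(labels, LabelVector) else np.asarray(labels, dtype=float).ravel()
    if len(b) != len(r):
        raise ValueError("coefficient and label vectors must have equal length")
    if centered:
        b = b - b.mean()
        r = r - r.mean()
    nb, nr = float(b @ b), float(r @ r)
    if nb <= 0 or nr <= 0:
        raise ValueError("undefined correlation: zero-norm vector")
    return float(abs(r @ b) / np.sqrt(nr * nb))


def select_by_correlation(coeff_matrix: np.ndarray, labels: LabelVector | np.ndarray,
                          top_k: int = 4, centered: bool = False) -> tuple[int, ...]:
    """Indices (1-based) of the top_k modes by label correlation.

    ``coeff_matrix`` is subjects x modes.  Ties break toward the smaller
    mode index; top_k larger than the mode count is clipped with a warning.
    """
    coeff_matrix = np.asarray(coeff_matrix, dtype=float)
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n_modes = coeff_matrix.shape[1]
    if top_k > n_modes:
        log.warning("top_k=%d exceeds available modes (%d); clipping", top_k, n_modes)
        top_k = n_modes
    corr = np.array([mode_label_correlation(coeff_matrix[:, j], labels, centered=centered)
                     for j in range(n_modes)])
    order = np.argsort(-corr, kind="stable")  # stable sort: ties keep smaller index first
    return tuple(int(j) + 1 for j in order[:top_k])


def select_by_avcr(model: ShapeModelResults, threshold: float = 0.90,
                   top_k: int | None = None) -> tuple[int, ...]:
    """Prefix of modes reaching the AVCR threshold (or the first top_k)."""
    if top_k is not None:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        return tuple(range(1, min(top_k, model.n_modes) + 1))
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    for k in range(1, model.n_modes + 1):
        if model.avcr(k) >= threshold - 1e-12:
            return tuple(range(1, k + 1))
    return tuple(range(1, model.n_modes + 1))


def combine_selections(avcr_set, corr_set, correlations: dict[int, float] | np.ndarray,
                       final_count: int | None = 1) -> ModeSelection:
    """Product set of the two selections, strongest-correlation first.

    ``correlations`` maps 1-based mode index to its label correlation (an
    array is read as correlations[i-1] for mode i).  An empty intersection
    falls back to the strongest-correlation mode inside the AVCR set, with
    a warning.
    """
    avcr_set, corr_set = tuple(avcr_set), tuple(corr_set)
    if not avcr_set or not corr_set:
        raise ValueError("both selections must be non-empty")
    if not isinstance(correlations, dict):
        arr = np.asarray(correlations, dtype=float)
        correlations = {j + 1: float(arr[j]) for j in range(len(arr))}
    inter = sorted(set(avcr_set) & set(corr_set),
                   key=lambda j: (-correlations.get(j, 0.0), j))
    fallback = False
    if not inter:
        fallback = True
        inter = [max(avcr_set, key=lambda j: (correlations.get(j, 0.0), -j))]
        log.warning("empty product set; falling back to mode %d (top correlation in AVCR set)",
                    inter[0])
    if final_count is not None:
        inter = inter[:final_count]
    return ModeSelection(avcr_set=avcr_set, corr_set=corr_set, selected=tuple(inter),
                         correlations={j: correlations.get(j, float("nan"))
                                       for j in set(avcr_set) | set(corr_set)},
                         fallback_used=fallback)


def select_modes(model: ShapeModelResults, coeff_matrix: np.ndarray,
                 labels: LabelVector | np.ndarray, avcr_threshold: float = 0.90,
                 corr_top_k: int = 4, final_count: int | None = 1,
                 centered: bool = False) -> ModeSelection:
    """Full combined selection for one fitted shape model."""
    coeff_matrix = np.asarray(coeff_matrix, dtype=float)
    avcr_set = select_by_avcr(model, threshold=avcr_threshold)
    corr_set = select_by_correlation(coeff_matrix, labels, top_k=corr_top_k, centered=centered)
    corrs = {j + 1: mode_label_correlation(coeff_matrix[:, j], labels, centered=centered)
             for j in range(coeff_matrix.shape[1])}
    return combine_selections(avcr_set, corr_set, corrs, final_count=final_count)
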