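"""Shared fixtures: analytic volumes, organ-like meshes, small cohorts."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from morphostage.surface import Surface
from morphostage.synthetic import CohortSpec, generate_cohort
from morphostage.volume import LabelVolume


@pytest.fixture(scope="session")
def digital_ball() -> tuple[LabelVolume, float]:
    """Solid digital ball of radius 10 voxels, unit spacing."""
    radius = 10
    n = radius + 4
    idx = np.indices((2 * n + 1,) * 3) - n
    grid = (np.sum(idx ** 2, axis=0) <= radius ** 2).astype(np.uint8)
    return LabelVolume(grid), float(radius)


@pytest.fixture(scope="session")
def organ_surface() -> Surface:
    """Asymmetric, chiral, closed genus-0 organ-like mesh (642 vertices)."""
    ico = trimesh.creation.icosphere(subdivisions=3)
    u = np.asarray(ico.vertices)
    bump1 = np.array([0.8, 0.4, 0.4]) / np.linalg.norm([0.8, 0.4, 0.4])
    bump2 = np.array([-0.3, 0.8, -0.5]) / np.linalg.norm([-0.3, 0.8, -0.5])
    r = (1.0
         + 0.35 * np.exp(-8 * np.sum((u - bump1) ** 2, axis=1))
         + 0.25 * np.exp(-6 * np.sum((u - bump2) ** 2, axis=1)))
    vertices = (u * r[:, None]) * np.array([80.0, 55.0, 45.0])
    return Surface(vertices, np.asarray(ico.faces), organ="liver")


@pytest.fixture(scope="session")
def dense_sphere() -> Surface:
    """Dense sphere mesh (2562 vertices) at organ scale."""
    ico = trimesh.creation.icosphere(subdivisions=4)
    return Surface(np.asarray(ico.vertices) * 70.0, np.asarray(ico.faces), organ="liver")


@pytest.fixture(scope="session")
def small_cohort():
    """Quick 14-subject staged cohort at 300 vertices, full nuisance variation."""
    return generate_cohort(CohortSpec(n_per_stage=(6, 4, 2), n_unstaged_abnormal=2,
                                      seed=3, vertex_count=300))


@pytest.fixture(scope="session")
def corresponded_cohort():
    """Corresponded (unpermuted, aligned) cohort for model-level tests.

    Misalignment and permutation are disabled so the shape vectors can be
    assembled directly in template order, bypassing matching.
    """
    return generate_cohort(CohortSpec(n_per_stage=(12, 6, 3), n_unstaged_abnormal=0,
                                      max_rotation_deg=0.0, max_translation_frac=0.0,
                                      permute_vertices=False, seed=7, vertex_count=162))


def cohort_vectors(cohort, variant: str) -> np.ndarray:
    """Stack a corresponded cohort into an (N, D) shape matrix."""
    rows = []
    for s in cohort:
        if variant == "joint":
            rows.append(np.concatenate([s.liver.vertices.ravel(), s.spleen.vertices.ravel()]))
        else:
            rows.append(getattr(s, variant).vertices.ravel())
    return np.stack(rows)
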