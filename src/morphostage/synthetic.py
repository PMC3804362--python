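"""Synthetic cohorts of paired liver-like and spleen-like surfaces.

Provides ground truth for the whole pipeline.  The morphology emulates
the qualitative signature of cirrhosis: with advancing stage the liver's
left lobe hypertrophies, the right lobe atrophies, and the spleen
enlarges.  Each organ is a star-shaped radial surface evaluated on a
fixed spherical template mesh:

* liver — union of two overlapping ellipsoidal lobes, both containing
  the origin, so the union stays star-shaped; the stage scales the left
  lobe by (1 + effect * stage) and the right by (1 - effect * stage);
* spleen — a single ellipsoid whose volume scales by (1 + effect * stage).

On top of the stage signal every subject receives a smooth random radial
deformation (low-order real spherical harmonics with per-coefficient
standard deviation decaying as 1/l^2), isotropic per-vertex jitter, a
random rigid misalignment shared by both organs, and (by default) a
random relabelling of its vertices — so index order carries no
correspondence information and the matcher has real work to do.  The
cohort structure mirrors a clinical staging table: counts per stage
0/1/2 plus abnormal subjects whose stage is unlabelled (binary label 1,
no stage target).  Everything derives from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .register import RigidTransform
from .surface import Surface, standardize_vertex_count
from .volume import LabelVolume

# lobe geometry in canonical liver coordinates (mm); every component
# contains the origin so each union is star-shaped about it.  The right
# lobe is ~4x the left by volume, matching real hepatic asymmetry; a
# clearly chiral shape also keeps rigid registration from locking onto a
# flipped attitude.
_LIVER_LOBES = (
    {"center": np.array([48.0, 18.0, -2.0]), "axes": np.array([62.0, 42.0, 36.0])},   # left
    {"center": np.array([-48.0, -5.0, 5.0]), "axes": np.array([92.0, 70.0, 58.0])},   # right
)
# caudate-like process: stage-independent chiral landmark (scaled by the
# mean of the two lobe factors, i.e. constant under the symmetric
# hypertrophy/atrophy effect)
_LIVER_CAUDATE = {"center": np.array([10.0, -30.0, 25.0]), "axes": np.array([50.0, 45.0, 40.0])}
# spleen: main body plus an offset polar bump -> asymmetric bean-like shape
_SPLEEN_PARTS = (
    {"center": np.array([-10.0, 0.0, 0.0]), "axes": np.array([55.0, 35.0, 27.0])},
    {"center": np.array([22.0, 10.0, 5.0]), "axes": np.array([34.0, 26.0, 20.0])},
)
_SPLEEN_OFFSET = np.array([-130.0, 70.0, 25.0])


@dataclass
class CohortSpec:
    """Study conditions of a synthetic cohort.

    Defaults mirror a 44-subject clinical cohort: 25 normal, 19
    cirrhotic of which 8 early and 2 middle/late stage carry labels and 9
    are unstaged.
    """

    n_per_stage: tuple[int, int, int] = (25, 8, 2)
    n_unstaged_abnormal: int = 9
    stage_effect: float = 0.15
    noise_sd: float = 0.02
    max_rotation_deg: float = 20.0
    max_translation_frac: float = 0.10
    deformation_sd: float = 0.04
    vertex_count: int = 1000
    permute_vertices: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_stage = tuple(int(n) for n in self.n_per_stage)
        if len(self.n_per_stage) != 3 or any(n < 0 for n in self.n_per_stage):
            raise ValueError("n_per_stage must be three non-negative counts")
        for name in ("stage_effect", "noise_sd", "max_rotation_deg",
                     "max_translation_frac", "deformation_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_n < 4:
            raise ValueError("cohort must contain at least 4 subjects")

    @property
    def total_n(self) -> int:
        return sum(self.n_per_stage) + self.n_unstaged_abnormal


@dataclass
class SyntheticSubject:
    subject_id: str
    liver: Surface
    spleen: Surface
    stage: int  # latent severity in {0, 1, 2}, always known to the generator
    stage_label: int | None  # None for unstaged abnormal subjects
    ground_truth: dict = field(default_factory=dict)

    @property
    def binary_label(self) -> int:
        return int(self.stage > 0)


@lru_cache(maxsize=4)
def _sphere_template(vertex_count: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere direction mesh with exactly ``vertex_count`` vertices."""
    import trimesh

    subdiv = 1
    while 10 * 4 ** subdiv + 2 < vertex_count:
        subdiv += 1
    ico = trimesh.creation.icosphere(subdivisions=subdiv)
    surf = Surface(np.asarray(ico.vertices), np.asarray(ico.faces))
    surf = standardize_vertex_count(surf, vertex_count)
    dirs = surf.vertices / np.linalg.norm(surf.vertices, axis=1, keepdims=True)
    return dirs, surf.faces


def _real_sph_harm(l: int, m: int, dirs: np.ndarray) -> np.ndarray:
    from scipy.special import sph_harm_y

    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])  # azimuth
    y = sph_harm_y(l, abs(m), theta, phi)
    if m == 0:
        return np.real(y)
    if m > 0:
        return np.sqrt(2.0) * (-1) ** m * np.real(y)
    return np.sqrt(2.0) * (-1) ** m * np.imag(y)


def _deformation_field(dirs: np.ndarray, rng: np.random.Generator, sd: float,
                       max_order: int = 4) -> tuple[np.ndarray, dict]:
    """Smooth radial modulation 1 + sum_lm c_lm Y_lm, c_lm ~ N(0, (sd/l^2)^2)."""
    mod = np.ones(len(dirs))
    coeffs = {}
    for l in range(1, max_order + 1):
        for m in range(-l, l + 1):
            c = rng.normal(0.0, sd / l ** 2)
            coeffs[(l, m)] = c
            if c != 0.0:
                mod = mod + c * _real_sph_harm(l, m, dirs)
    return mod, coeffs


def _ellipsoid_ray_exit(dirs: np.ndarray, center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """Distance from the origin to the ellipsoid surface along each direction
    (0 where the ray misses).  The origin may lie inside or outside."""
    inv2 = 1.0 / axes ** 2
    a2 = np.sum(dirs ** 2 * inv2, axis=1)
    a1 = -2.0 * np.sum(dirs * (center * inv2), axis=1)
    a0 = float(np.sum(center ** 2 * inv2) - 1.0)
    disc = a1 ** 2 - 4.0 * a2 * a0
    t = np.zeros(len(dirs))
    hit = disc >= 0
    t[hit] = (-a1[hit] + np.sqrt(disc[hit])) / (2.0 * a2[hit])
    return np.maximum(t, 0.0)


def liver_radius(dirs: np.ndarray, stage_severity: float, stage_effect: float) -> np.ndarray:
    """Radial function of the two-lobe liver at a given severity."""
    # stage_effect acts on lobe *volume* (like the spleen): +-30% linear
    # scale per step would invert the liver's left/right asymmetry by
    # stage 2, which no cirrhotic liver does
    k_left = (1.0 + stage_effect * stage_severity) ** (1.0 / 3.0)
    k_right = (1.0 - stage_effect * stage_severity) ** (1.0 / 3.0)
    k_mid = 0.5 * (k_left + k_right)
    r = np.zeros(len(dirs))
    for lobe, k in zip((*_LIVER_LOBES, _LIVER_CAUDATE), (k_left, k_right, k_mid)):
        r = np.maximum(r, _ellipsoid_ray_exit(dirs, k * lobe["center"], k * lobe["axes"]))
    return r


def spleen_radius(dirs: np.ndarray, stage_severity: float, stage_effect: float) -> np.ndarray:
    """Radial function of the spleen; volume scales by (1 + effect * severity)."""
    k = (1.0 + stage_effect * stage_severity) ** (1.0 / 3.0)
    r = np.zeros(len(dirs))
    for part in _SPLEEN_PARTS:
        r = np.maximum(r, _ellipsoid_ray_exit(dirs, k * part["center"], k * part["axes"]))
    return r


def _random_rigid(rng: np.random.Generator, max_rot_deg: float, max_trans: float) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rot_deg))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    trans = rng.uniform(-max_trans, max_trans, size=3)
    return RigidTransform(rot, trans)


def _permuted(vertices: np.ndarray, faces: np.ndarray,
              rng: np.random.Generator, enabled: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(vertices)
    if not enabled:
        return vertices, faces, np.arange(n)
    perm = rng.permutation(n)  # new_vertices[j] = vertices[perm[j]]
    inverse = np.empty(n, dtype=np.int64)
    inverse[perm] = np.arange(n)
    return vertices[perm], inverse[faces], perm


def generate_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate the cohort; bit-identical for a fixed spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    dirs, faces = _sphere_template(spec.vertex_count)

    stages: list[tuple[int, int | None]] = []  # (latent stage, stage label)
    for stage, count in enumerate(spec.n_per_stage):
        stages += [(stage, stage)] * count
    # unstaged cirrhotic subjects: latent severity drawn from the labelled
    # abnormal mix (early stage far more prevalent than middle/late)
    n1, n2 = spec.n_per_stage[1], spec.n_per_stage[2]
    p_middle = n2 / (n1 + n2) if (n1 + n2) else 0.5
    for _ in range(spec.n_unstaged_abnormal):
        stages.append((2 if rng.random() < p_middle else 1, None))

    subjects = []
    width = max(3, len(str(len(stages))))
    for i, (stage, label) in enumerate(stages):
        sid = f"s{i + 1:0{width}d}"
        rigid = _random_rigid(rng, spec.max_rotation_deg, spec.max_translation_frac *
                              float(np.mean(_LIVER_LOBES[1]["axes"])))
        organs = {}
        truth = {"stage": stage, "rigid": rigid}
        for organ, radius_fn, size_scale in (
                ("liver", liver_radius, float(np.mean(_LIVER_LOBES[1]["axes"]))),
                ("spleen", spleen_radius, float(np.mean(_SPLEEN_PARTS[0]["axes"])))):
            mod, coeffs = _deformation_field(dirs, rng, spec.deformation_sd)
            r = radius_fn(dirs, float(stage), spec.stage_effect) * mod
            verts = dirs * r[:, None]
            if organ == "spleen":
                verts = verts + _SPLEEN_OFFSET
            if spec.noise_sd > 0:
                verts = verts + rng.normal(0.0, spec.noise_sd * size_scale, size=verts.shape)
            verts = rigid.apply(verts)
            verts, f, perm = _permuted(verts, faces, rng, spec.permute_vertices)
            organs[organ] = Surface(verts, f, organ=organ, subject_id=sid)
            truth[f"{organ}_deformation"] = coeffs
            truth[f"{organ}_permutation"] = perm
        subjects.append(SyntheticSubject(subject_id=sid, liver=organs["liver"],
                                         spleen=organs["spleen"], stage=stage,
                                         stage_label=label, ground_truth=truth))
    return subjects


def cohort_to_label_table(cohort: list[SyntheticSubject]) -> pd.DataFrame:
    """Label table with one row per subject.

    ``binary_label`` is 0 for normal and 1 for any cirrhotic subject;
    ``stage_label`` is the 0/1/2 stage, NA where unstaged.
    """
    rows = [{"subject_id": s.subject_id, "binary_label": s.binary_label,
             "stage_label": s.stage_label} for s in cohort]
    df = pd.DataFrame(rows, columns=["subject_id", "binary_label", "stage_label"])
    df["stage_label"] = df["stage_label"].astype("Int64")
    return df


def voxelize_surface(surface: Surface, spacing: float = 4.0, margin: float = 8.0) -> LabelVolume:
    """Rasterize a closed surface to a binary label volume (parity fill).

    Casts one ray per (y, z) grid column along +x, collects triangle
    crossings, and fills between successive pairs.  Intended for
    exercising the volume pathway on synthetic organs.
    """
    verts, faces = surface.vertices, surface.faces
    lo = verts.min(axis=0) - margin
    hi = verts.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    grid = np.zeros(shape, dtype=np.uint8)
    ny, nz = shape[1], shape[2]
    yy = lo[1] + spacing * np.arange(ny)
    zz = lo[2] + spacing * np.arange(nz)
    crossings: dict[tuple[int, int], list[float]] = {}
    tri = verts[faces]
    for t in tri:
        v0, e1, e2 = t[0], t[1] - t[0], t[2] - t[0]
        det = e1[1] * e2[2] - e1[2] * e2[1]  # 2x2 system in the (y, z) plane
        if abs(det) < 1e-12:
            continue
        ymin, ymax = t[:, 1].min(), t[:, 1].max()
        zmin, zmax = t[:, 2].min(), t[:, 2].max()
        iy = np.nonzero((yy >= ymin) & (yy <= ymax))[0]
        iz = np.nonzero((zz >= zmin) & (zz <= zmax))[0]
        if not len(iy) or not len(iz):
            continue
        gy, gz = np.meshgrid(yy[iy], zz[iz], indexing="ij")
        by = gy - v0[1]
        bz = gz - v0[2]
        u = (by * e2[2] - bz * e2[1]) / det
        w = (bz * e1[1] - by * e1[2]) / det
        inside = (u >= 0) & (w >= 0) & (u + w <= 1)
        if not inside.any():
            continue
        xcross = v0[0] + u * e1[0] + w * e2[0]
        ii, jj = np.nonzero(inside)
        for a, b, xc in zip(iy[ii], iz[jj], xcross[inside]):
            crossings.setdefault((int(a), int(b)), []).append(float(xc))
    xs = lo[0] + spacing * np.arange(shape[0])
    for (a, b), cuts in crossings.items():
        cuts.sort()
        for k in range(0, len(cuts) - 1, 2):
            grid[(xs >= cuts[k]) & (xs <= cuts[k + 1]), a, b] = 1
    return LabelVolume(grid, (spacing,) * 3, tuple(lo), organ=surface.organ)
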