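"""Quadric-error-metric edge collapse to an exact vertex count.

Garland-Heckbert style simplification specialised for closed manifold
organ meshes: area-weighted plane quadrics, optimal collapse placement
with midpoint/endpoint fallback, link-condition and normal-flip guards so
the mesh stays closed and embedded.  Fully deterministic: the collapse
queue breaks cost ties by vertex index.
"""

from __future__ import annotations

import heapq

import numpy as np


def _face_quadric(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    n = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(n)
    if area2 < 1e-30:
        return np.zeros((4, 4))
    n_hat = n / area2
    d = -float(n_hat @ p0)
    plane = np.append(n_hat, d)
    return 0.5 * area2 * np.outer(plane, plane)


def _optimal_point(q: np.ndarray, pu: np.ndarray, pv: np.ndarray) -> tuple[np.ndarray, float]:
    a, b = q[:3, :3], q[:3, 3]
    candidates = [pu, pv, 0.5 * (pu + pv)]
    if abs(np.linalg.det(a)) > 1e-12 * (np.trace(a) / 3.0 + 1e-30) ** 3:
        try:
            candidates.insert(0, np.linalg.solve(a, -b))
        except np.linalg.LinAlgError:
            pass
    best, best_cost = None, np.inf
    for p in candidates:
        h = np.append(p, 1.0)
        cost = float(h @ q @ h)
        if cost < best_cost:
            best, best_cost = p, cost
    return best, max(best_cost, 0.0)


class _Mesh:
    """Mutable halfedge-free mesh state for the collapse loop."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.pos = {i: vertices[i].astype(float).copy() for i in range(len(vertices))}
        self.faces: dict[int, tuple[int, int, int]] = {i: tuple(f) for i, f in enumerate(faces)}
        self.v_faces: dict[int, set[int]] = {i: set() for i in self.pos}
        for fid, f in self.faces.items():
            for v in f:
                self.v_faces[v].add(fid)
        self.quadric = {i: np.zeros((4, 4)) for i in self.pos}
        for f in self.faces.values():
            kq = _face_quadric(*(self.pos[v] for v in f))
            for v in f:
                self.quadric[v] += kq
        self.version = {i: 0 for i in self.pos}

    def neighbours(self, v: int) -> set[int]:
        out: set[int] = set()
        for fid in self.v_faces[v]:
            out.update(self.faces[fid])
        out.discard(v)
        return out

    def collapse_ok(self, u: int, v: int, new_pos: np.ndarray) -> bool:
        # link condition: exactly two common neighbours on a closed manifold
        if len(self.neighbours(u) & self.neighbours(v)) != 2:
            return False
        # reject collapses that flip or degenerate any surviving face
        for keep, other in ((u, v), (v, u)):
            for fid in self.v_faces[keep]:
                f = self.faces[fid]
                if other in f:
                    continue  # face dies with the collapse
                old = [self.pos[w] for w in f]
                new = [new_pos if w == keep else self.pos[w] for w in f]
                n_old = np.cross(old[1] - old[0], old[2] - old[0])
                n_new = np.cross(new[1] - new[0], new[2] - new[0])
                norm = np.linalg.norm(n_old) * np.linalg.norm(n_new)
                if norm < 1e-30 or float(n_old @ n_new) / norm < 1e-4:
                    return False
        return True

    def collapse(self, u: int, v: int, new_pos: np.ndarray) -> set[int]:
        """Merge v into u placed at new_pos; return vertices whose star changed."""
        touched = self.neighbours(u) | self.neighbours(v) | {u}
        dead = self.v_faces[u] & self.v_faces[v]
        for fid in dead:
            for w in self.faces[fid]:
                self.v_faces[w].discard(fid)
            del self.faces[fid]
        for fid in list(self.v_faces[v]):
            f = self.faces[fid]
            self.faces[fid] = tuple(u if w == v else w for w in f)
            self.v_faces[u].add(fid)
        del self.v_faces[v]
        del self.pos[v]
        self.pos[u] = new_pos
        self.quadric[u] = self.quadric[u] + self.quadric[v]
        del self.quadric[v]
        del self.version[v]
        touched.discard(v)
        for w in touched:
            self.version[w] += 1
        return touched


def decimate_qem(vertices: np.ndarray, faces: np.ndarray, target_count: int):
    """Collapse edges until exactly ``target_count`` vertices remain.

    Returns (vertices, faces) with vertices reindexed in increasing
    original-id order, which makes the output deterministic.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    if target_count >= len(vertices):
        return vertices.copy(), faces.copy()
    mesh = _Mesh(vertices, faces)

    heap: list[tuple] = []

    def push_edges(vs):
        for a in vs:
            if a not in mesh.pos:
                continue
            for b in mesh.neighbours(a):
                u, v = (a, b) if a < b else (b, a)
                q = mesh.quadric[u] + mesh.quadric[v]
                p, cost = _optimal_point(q, mesh.pos[u], mesh.pos[v])
                heapq.heappush(heap, (cost, u, v, mesh.version[u], mesh.version[v], tuple(p)))

    push_edges(list(mesh.pos))
    while len(mesh.pos) > target_count:
        if not heap:
            raise RuntimeError("decimation stalled before reaching target vertex count")
        cost, u, v, ver_u, ver_v, p = heapq.heappop(heap)
        if u not in mesh.pos or v not in mesh.pos:
            continue
        if mesh.version[u] != ver_u or mesh.version[v] != ver_v:
            continue
        new_pos = np.asarray(p)
        if not mesh.collapse_ok(u, v, new_pos):
            continue
        touched = mesh.collapse(u, v, new_pos)
        push_edges(sorted(touched))

    old_ids = sorted(mesh.pos)
    remap = {old: new for new, old in enumerate(old_ids)}
    out_vertices = np.array([mesh.pos[i] for i in old_ids])
    out_faces = np.array([[remap[w] for w in mesh.faces[fid]] for fid in sorted(mesh.faces)],
                         dtype=np.int64)
    return out_vertices, out_faces
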