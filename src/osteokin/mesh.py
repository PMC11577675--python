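"""Minimal closed-triangle-mesh type with plane clipping and STL/PLY I/O.

Only the operations the osteotomy pipeline needs are implemented: signed
volume, watertightness/topology checks, half-space clipping with planar
caps, mirroring, concatenation, and (binary or ASCII) STL plus ASCII PLY
export/import. Meshes are vertex/face arrays; faces are CCW-outward.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .geometry import Plane, unit

_SNAP = 1e-12  # |signed distance| below which a vertex counts as on-plane


@dataclass
class TriMesh:
    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64, CCW when viewed from outside

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    # ---------------------------------------------------------------- props

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return self.n_faces == 0

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def volume(self) -> float:
        """Signed volume via the divergence theorem (positive if outward CCW)."""
        if self.is_empty():
            return 0.0
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def _edge_counts(self):
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        directed = {}
        for a, b in e:
            directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
        return directed

    def is_watertight(self) -> bool:
        """Every directed edge matched by exactly one opposite directed edge."""
        if self.is_empty():
            return False
        directed = self._edge_counts()
        for (a, b), n in directed.items():
            if n != 1 or directed.get((b, a), 0) != 1:
                return False
        return True

    def euler_characteristic(self) -> int:
        used = np.unique(self.faces)
        directed = self._edge_counts()
        n_edges = len({(min(a, b), max(a, b)) for a, b in directed})
        return int(len(used) - n_edges + self.n_faces)

    def n_components(self) -> int:
        """Connected components over face-adjacency (shared vertices)."""
        if self.is_empty():
            return 0
        parent = list(range(self.n_vertices))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for f in self.faces:
            a = find(int(f[0]))
            for v in f[1:]:
                b = find(int(v))
                parent[b] = a
        roots = {find(int(v)) for v in np.unique(self.faces)}
        return len(roots)

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # ------------------------------------------------------------- editing

    def mirrored(self, axis: int = 0) -> "TriMesh":
        """Reflect through the plane {x_axis = 0}; winding reversed to stay outward."""
        v = self.vertices.copy()
        v[:, axis] *= -1.0
        f = self.faces[:, ::-1].copy()
        return TriMesh(v, f)

    @staticmethod
    def concatenate(meshes: list["TriMesh"]) -> "TriMesh":
        meshes = [m for m in meshes if not m.is_empty()]
        if not meshes:
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
        verts, faces, off = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + off)
            off += m.n_vertices
        return TriMesh(np.vstack(verts), np.vstack(faces))

    # ------------------------------------------------------------- clipping

    def clip_halfspace(self, plane: Plane) -> "TriMesh":
        """Return the closed part of the solid with signed distance <= 0.

        The planar cross-section is capped with ear-clipped polygons whose
        outward normal is +plane.normal. Input must be watertight; output is
        watertight (or empty) for meshes in general position.
        """
        if self.is_empty():
            return self.copy()
        sd = plane.signed_distance(self.vertices)
        # vertices exactly on the plane break the cap-boundary chaining;
        # nudge the plane by a deterministic, sub-nanometre offset instead
        nudge = 0.0
        while np.any(np.abs(sd) < _SNAP):
            nudge += 1e-9
            if nudge > 1e-6:
                raise ValueError("cannot separate plane from mesh vertices")
            sd = plane.signed_distance(self.vertices) - nudge
        if np.all(sd <= 0):
            return self.copy()
        if np.all(sd >= 0):
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))

        new_verts: list[np.ndarray] = []
        vert_map: dict = {}  # ('v', i) or ('e', i, j) -> new index

        def old_vertex(i: int) -> int:
            key = ("v", i)
            if key not in vert_map:
                vert_map[key] = len(new_verts)
                new_verts.append(self.vertices[i])
            return vert_map[key]

        def edge_vertex(i: int, j: int) -> int:
            key = ("e", min(i, j), max(i, j))
            if key not in vert_map:
                # computed symmetrically so both adjacent faces share it exactly
                a, b = key[1], key[2]
                da, db = sd[a], sd[b]
                t = da / (da - db)
                p = self.vertices[a] + t * (self.vertices[b] - self.vertices[a])
                vert_map[key] = len(new_verts)
                new_verts.append(p)
            return vert_map[key]

        faces_out: list[tuple] = []
        boundary: dict = {}  # start key -> end key along kept-region boundary

        for tri in self.faces:
            ids = [int(x) for x in tri]
            d = [sd[i] for i in ids]
            if all(x <= 0 for x in d):
                faces_out.append(tuple(old_vertex(i) for i in ids))
                continue
            if all(x >= 0 for x in d):
                continue
            # build clipped polygon (Sutherland–Hodgman against sd<=0)
            poly: list[int] = []
            bkeys: list[tuple | None] = []  # boundary key per polygon vertex
            for k in range(3):
                i, j = ids[k], ids[(k + 1) % 3]
                di, dj = d[k], d[(k + 1) % 3]
                if di <= 0:
                    poly.append(old_vertex(i))
                    bkeys.append(("v", i) if di == 0 else None)
                if (di < 0 < dj) or (dj < 0 < di):
                    poly.append(edge_vertex(i, j))
                    bkeys.append(("e", min(i, j), max(i, j)))
            if len(poly) < 3:
                continue
            for k in range(1, len(poly) - 1):
                faces_out.append((poly[0], poly[k], poly[k + 1]))
            # record boundary edge(s): consecutive polygon vertices that both
            # lie on the plane, ordered as traversed (kept region to the left)
            npoly = len(poly)
            for k in range(npoly):
                ka, kb = bkeys[k], bkeys[(k + 1) % npoly]
                if ka is not None and kb is not None and ka != kb:
                    boundary[ka] = kb

        cap_faces = _cap_loops(boundary, vert_map, new_verts, plane)
        faces_out.extend(cap_faces)
        verts = np.array(new_verts) if new_verts else np.zeros((0, 3))
        faces = (
            np.array(faces_out, dtype=np.int64)
            if faces_out
            else np.zeros((0, 3), dtype=np.int64)
        )
        return TriMesh(verts, faces)

    # ------------------------------------------------------------------ I/O

    def save_stl(self, path, binary: bool = True, name: str = "osteokin") -> None:
        v = self.vertices
        tris = v[self.faces]
        n = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
        norms = np.linalg.norm(n, axis=1)
        norms[norms == 0] = 1.0
        n = n / norms[:, None]
        if binary:
            with open(path, "wb") as fh:
                fh.write(name.encode().ljust(80, b"\0"))
                fh.write(struct.pack("<I", len(tris)))
                for ni, tri in zip(n, tris):
                    fh.write(struct.pack("<3f", *ni))
                    for p in tri:
                        fh.write(struct.pack("<3f", *p))
                    fh.write(struct.pack("<H", 0))
        else:
            with open(path, "w") as fh:
                fh.write(f"solid {name}\n")
                for ni, tri in zip(n, tris):
                    fh.write(f"facet normal {ni[0]:.9e} {ni[1]:.9e} {ni[2]:.9e}\n")
                    fh.write("outer loop\n")
                    for p in tri:
                        fh.write(f"vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
                    fh.write("endloop\nendfacet\n")
                fh.write(f"endsolid {name}\n")

    @classmethod
    def load_stl(cls, path) -> "TriMesh":
        with open(path, "rb") as fh:
            head = fh.read(80)
            rest = fh.read()
        if head[:5] == b"solid" and b"facet" in rest[:2000] + head:
            text = (head + rest).decode(errors="replace")
            pts = []
            for line in text.splitlines():
                line = line.strip()
                if line.startswith("vertex"):
                    pts.append([float(x) for x in line.split()[1:4]])
            tri_pts = np.array(pts).reshape(-1, 3, 3)
        else:
            (count,) = struct.unpack_from("<I", rest, 0)
            data = np.frombuffer(rest, dtype=np.uint8, count=count * 50, offset=4)
            rec = data.reshape(count, 50)
            tri_pts = (
                rec[:, 12:48].copy().view("<f4").reshape(count, 3, 3).astype(float)
            )
        return cls._from_triangle_soup(tri_pts)

    def save_ply(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {self.n_vertices}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write(f"element face {self.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for p in self.vertices:
                fh.write(f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}\n")
            for f in self.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")

    @classmethod
    def load_ply(cls, path) -> "TriMesh":
        with open(path) as fh:
            lines = fh.read().splitlines()
        nv = nf = 0
        i = 0
        while lines[i].strip() != "end_header":
            tok = lines[i].split()
            if tok[:2] == ["element", "vertex"]:
                nv = int(tok[2])
            elif tok[:2] == ["element", "face"]:
                nf = int(tok[2])
            i += 1
        verts = np.array(
            [[float(x) for x in lines[i + 1 + k].split()[:3]] for k in range(nv)]
        )
        faces = np.array(
            [[int(x) for x in lines[i + 1 + nv + k].split()[1:4]] for k in range(nf)],
            dtype=np.int64,
        )
        return cls(verts, faces)

    @classmethod
    def _from_triangle_soup(cls, tri_pts: np.ndarray) -> "TriMesh":
        flat = tri_pts.reshape(-1, 3)
        uniq, inv = np.unique(
            flat.round(decimals=7), axis=0, return_inverse=True
        )
        faces = inv.reshape(-1, 3).astype(np.int64)
        return cls(uniq, faces)


# ------------------------------------------------------------------ capping


def _cap_loops(boundary, vert_map, new_verts, plane: Plane) -> list[tuple]:
    """Chain boundary edges into closed loops and ear-clip each into triangles."""
    if not boundary:
        return []
    faces: list[tuple] = []
    # plane basis
    n = plane.normal
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = unit(np.cross(n, helper))
    v = np.cross(n, u)

    remaining = dict(boundary)
    while remaining:
        start = next(iter(remaining))
        loop_keys = [start]
        cur = remaining.pop(start)
        guard = 0
        while cur != start:
            loop_keys.append(cur)
            if cur not in remaining:
                raise ValueError("open cross-section boundary; mesh not watertight?")
            cur = remaining.pop(cur)
            guard += 1
            if guard > 10_000_000:
                raise ValueError("boundary chaining did not terminate")
        idx = [vert_map[k] for k in loop_keys]
        pts3 = np.array([new_verts[i] for i in idx])
        pts2 = np.column_stack([pts3 @ u, pts3 @ v])
        # boundary traversal leaves kept solid on the interior side such that
        # the cap, wound in traversal order, faces +normal; enforce via area
        area = _polygon_area(pts2)
        if area < 0:
            idx.reverse()
            pts2 = pts2[::-1]
        faces.extend(_ear_clip(idx, pts2))
    return faces


def _polygon_area(pts2: np.ndarray) -> float:
    x, y = pts2[:, 0], pts2[:, 1]
    return 0.5 * float(
        np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    )


def _ear_clip(idx: list[int], pts2: np.ndarray) -> list[tuple]:
    """Triangulate a simple CCW polygon by ear clipping."""
    n = len(idx)
    if n < 3:
        return []
    order = list(range(n))
    tris: list[tuple] = []
    guard = 0
    while len(order) > 3:
        guard += 1
        if guard > 4 * n * n:
            # fall back: fan (only hit for degenerate slivers)
            o = order
            tris.extend((idx[o[0]], idx[o[k]], idx[o[k + 1]]) for k in range(1, len(o) - 1))
            return tris
        m = len(order)
        clipped = False
        for k in range(m):
            ia, ib, ic = order[(k - 1) % m], order[k], order[(k + 1) % m]
            a, b, c = pts2[ia], pts2[ib], pts2[ic]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:
                continue  # reflex or degenerate corner
            ear = True
            for j in order:
                if j in (ia, ib, ic):
                    continue
                if _point_in_tri(pts2[j], a, b, c):
                    ear = False
                    break
            if ear:
                tris.append((idx[ia], idx[ib], idx[ic]))
                order.pop(k)
                clipped = True
                break
        if not clipped:
            o = order
            tris.extend((idx[o[0]], idx[o[k]], idx[o[k + 1]]) for k in range(1, len(o) - 1))
            return tris
    tris.append((idx[order[0]], idx[order[1]], idx[order[2]]))
    return tris


def _point_in_tri(p, a, b, c) -> bool:
    d1 = (p[0] - b[0]) * (a[1] - b[1]) - (a[0] - b[0]) * (p[1] - b[1])
    d2 = (p[0] - c[0]) * (b[1] - c[1]) - (b[0] - c[0]) * (p[1] - c[1])
    d3 = (p[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (p[1] - a[1])
    neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (neg and pos)
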