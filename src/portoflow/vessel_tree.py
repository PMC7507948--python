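"""Portal venous tree: data model, validation, layout and surface meshing.

The portal venous system is represented as a graph of tapered circular
segments (portal vein trunk, left/right portal branches, splenic, superior
and inferior mesenteric veins) joined at shared junction nodes.  Boundary
faces sit on degree-1 nodes and carry the roles the flow solver needs:
``inlet`` (splanchnic supply), ``outlet`` (hepatic branches) and exactly one
``reference_outlet`` (the gauge-0 pressure reference on the portal trunk).

The triangulated surface produced here is for export and visual/area
cross-checks only; the network solver works directly on the segment
geometry.
"""
from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError, TopologyError, ValidationError

VESSEL_NAMES = frozenset(
    {
        "portal_vein",
        "left_portal",
        "right_portal",
        "splenic",
        "superior_mesenteric",
        "inferior_mesenteric",
        "other",
    }
)

FACE_ROLES = frozenset({"inlet", "outlet", "reference_outlet"})

#: Table of control-group vessel inner diameters (mm) used by the canonical
#: template.
CONTROL_DIAMETERS_MM = {
    "portal_vein": 4.5,
    "left_portal": 3.4,
    "right_portal": 4.2,
    "splenic": 1.8,
    "superior_mesenteric": 3.1,
    "inferior_mesenteric": 2.0,
}

#: Segment lengths (mm) for the canonical canine template.  Lengths are
#: package defaults chosen at anatomical plausibility for a beagle-sized dog;
#: they are not measured values.
DEFAULT_LENGTHS_MM = {
    "portal_vein": 45.0,
    "left_portal": 30.0,
    "right_portal": 30.0,
    "splenic": 60.0,
    "superior_mesenteric": 70.0,
    "inferior_mesenteric": 60.0,
}

#: Length (mm) of the zero-flow stub that hosts the pressure-reference face.
REFERENCE_STUB_LENGTH_MM = 2.0

#: The triangular surface-grid edge-length band (mm) enforced by
#: :func:`tube_surface_mesh`.
MESH_EDGE_BAND_MM = (0.2, 1.0)


@dataclass(frozen=True)
class VesselSegment:
    """One tapered circular vessel segment between two nodes."""

    id: str
    name: str
    length_mm: float
    d_prox_mm: float
    d_dist_mm: float
    node_prox: str
    node_dist: str


@dataclass(frozen=True)
class BoundaryFace:
    """An open cross-section of the tree where a boundary condition applies."""

    id: str
    node: str
    diameter_mm: float
    role: str


@dataclass
class VesselTree:
    segments: list[VesselSegment]
    faces: dict[str, BoundaryFace] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for s in self.segments:
            out.add(s.node_prox)
            out.add(s.node_dist)
        return out

    def degree(self, node: str) -> int:
        return sum(1 for s in self.segments if node in (s.node_prox, s.node_dist))

    def segments_at(self, node: str) -> list[VesselSegment]:
        return [s for s in self.segments if node in (s.node_prox, s.node_dist)]

    def segment_by_name(self, name: str) -> VesselSegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise ConfigurationError(f"tree has no segment named {name!r}")

    def face_segment(self, face_id: str) -> VesselSegment:
        """The unique segment whose end carries the given boundary face."""
        face = self.faces[face_id]
        segs = self.segments_at(face.node)
        if len(segs) != 1:
            raise TopologyError(
                f"face {face_id!r} node {face.node!r} has degree {len(segs)}, expected 1"
            )
        return segs[0]

    @property
    def reference_face(self) -> BoundaryFace:
        refs = [f for f in self.faces.values() if f.role == "reference_outlet"]
        if len(refs) != 1:
            raise ConfigurationError(
                f"tree has {len(refs)} reference_outlet faces, expected exactly 1"
            )
        return refs[0]


def validate_tree(tree: VesselTree) -> list[str]:
    """Return a description of every violated invariant (empty list = valid).

    Reports rather than raises, so callers can collect all defects of a
    hand-written tree specification at once.
    """
    violations: list[str] = []
    seg_ids: set[str] = set()
    for s in tree.segments:
        if s.id in seg_ids:
            violations.append(f"segment {s.id!r}: duplicate id")
        seg_ids.add(s.id)
        if s.name not in VESSEL_NAMES:
            violations.append(f"segment {s.id!r}: unknown vessel name {s.name!r}")
        for attr in ("length_mm", "d_prox_mm", "d_dist_mm"):
            v = getattr(s, attr)
            if not (v > 0) or not math.isfinite(v):
                violations.append(f"segment {s.id!r}: {attr} = {v} must be > 0")
        if s.node_prox == s.node_dist:
            violations.append(f"segment {s.id!r}: node_prox equals node_dist")

    nodes = tree.nodes
    # connectivity by union of segment endpoints
    if tree.segments:
        seen = {tree.segments[0].node_prox}
        frontier = [tree.segments[0].node_prox]
        adj: dict[str, list[str]] = {}
        for s in tree.segments:
            adj.setdefault(s.node_prox, []).append(s.node_dist)
            adj.setdefault(s.node_dist, []).append(s.node_prox)
        while frontier:
            n = frontier.pop()
            for m in adj.get(n, []):
                if m not in seen:
                    seen.add(m)
                    frontier.append(m)
        for n in sorted(nodes - seen):
            violations.append(f"node {n!r}: disconnected from the rest of the tree")

    face_nodes: set[str] = set()
    n_ref = 0
    for f in tree.faces.values():
        if f.role not in FACE_ROLES:
            violations.append(f"face {f.id!r}: unknown role {f.role!r}")
        if f.role == "reference_outlet":
            n_ref += 1
        if not (f.diameter_mm > 0):
            violations.append(f"face {f.id!r}: diameter {f.diameter_mm} must be > 0")
        if f.node not in nodes:
            violations.append(f"face {f.id!r}: node {f.node!r} not in tree")
        elif tree.degree(f.node) != 1:
            violations.append(
                f"face {f.id!r}: node {f.node!r} has degree {tree.degree(f.node)}, "
                "boundary faces must sit on degree-1 nodes"
            )
        face_nodes.add(f.node)
    if n_ref != 1:
        violations.append(f"tree has {n_ref} reference_outlet faces, expected exactly 1")
    for n in sorted(nodes):
        if tree.degree(n) == 1 and n not in face_nodes:
            violations.append(f"node {n!r}: degree-1 node without a boundary face")
    return violations


def build_tree(tree_spec: dict) -> VesselTree:
    """Construct and validate a :class:`VesselTree` from a JSON-style dict.

    Expected document shape::

        {"segments": [{"id", "name", "length_mm", "d_prox_mm", "d_dist_mm",
                       "nodes": [prox, dist]}],
         "faces":    [{"id", "node", "diameter_mm", "role"}]}

    Raises :class:`TopologyError` for disconnected graphs,
    :class:`ValidationError` for non-physical dimensions, and
    :class:`ConfigurationError` when the reference outlet is missing or
    duplicated.
    """
    segs_spec = tree_spec.get("segments", [])
    if not segs_spec:
        raise ConfigurationError("tree spec lists no segments")
    segments = []
    for d in segs_spec:
        try:
            nodes = d["nodes"]
            segments.append(
                VesselSegment(
                    id=str(d["id"]),
                    name=str(d["name"]),
                    length_mm=float(d["length_mm"]),
                    d_prox_mm=float(d["d_prox_mm"]),
                    d_dist_mm=float(d["d_dist_mm"]),
                    node_prox=str(nodes[0]),
                    node_dist=str(nodes[1]),
                )
            )
        except (KeyError, IndexError, TypeError) as exc:
            raise ConfigurationError(f"malformed segment entry {d!r}: {exc}") from exc
    faces = {}
    for d in tree_spec.get("faces", []):
        try:
            f = BoundaryFace(
                id=str(d["id"]),
                node=str(d["node"]),
                diameter_mm=float(d["diameter_mm"]),
                role=str(d["role"]),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed face entry {d!r}: {exc}") from exc
        if f.id in faces:
            raise ConfigurationError(f"duplicate face id {f.id!r}")
        faces[f.id] = f
    tree = VesselTree(segments=segments, faces=faces)
    violations = validate_tree(tree)
    if violations:
        msg = "; ".join(violations)
        if any("disconnected" in v for v in violations):
            raise TopologyError(msg)
        if any("reference_outlet" in v for v in violations):
            raise ConfigurationError(msg)
        raise ValidationError(msg)
    return tree


def canonical_tree_spec(diameters_mm: dict[str, float] | None = None) -> dict:
    """JSON-style spec of the canonical canine portal venous template.

    Six named vessels (diameters default to the control-group values) plus a
    short zero-flow stub carrying the pressure-reference face at the trunk's
    hepatic (distal) end.  Splenic, superior and inferior mesenteric veins
    drain into the confluence; the trunk runs confluence -> bifurcation; the
    left and right portal branches leave the bifurcation toward the liver.
    """
    d = dict(CONTROL_DIAMETERS_MM)
    if diameters_mm:
        d.update(diameters_mm)
    L = DEFAULT_LENGTHS_MM
    segments = [
        {"id": "sv", "name": "splenic", "length_mm": L["splenic"],
         "d_prox_mm": d["splenic"], "d_dist_mm": d["splenic"], "nodes": ["n_sv", "n_conf"]},
        {"id": "smv", "name": "superior_mesenteric", "length_mm": L["superior_mesenteric"],
         "d_prox_mm": d["superior_mesenteric"], "d_dist_mm": d["superior_mesenteric"],
         "nodes": ["n_smv", "n_conf"]},
        {"id": "imv", "name": "inferior_mesenteric", "length_mm": L["inferior_mesenteric"],
         "d_prox_mm": d["inferior_mesenteric"], "d_dist_mm": d["inferior_mesenteric"],
         "nodes": ["n_imv", "n_conf"]},
        {"id": "pv", "name": "portal_vein", "length_mm": L["portal_vein"],
         "d_prox_mm": d["portal_vein"], "d_dist_mm": d["portal_vein"],
         "nodes": ["n_conf", "n_bif"]},
        {"id": "lpv", "name": "left_portal", "length_mm": L["left_portal"],
         "d_prox_mm": d["left_portal"], "d_dist_mm": d["left_portal"],
         "nodes": ["n_bif", "n_lpv"]},
        {"id": "rpv", "name": "right_portal", "length_mm": L["right_portal"],
         "d_prox_mm": d["right_portal"], "d_dist_mm": d["right_portal"],
         "nodes": ["n_bif", "n_rpv"]},
        {"id": "ref_stub", "name": "other", "length_mm": REFERENCE_STUB_LENGTH_MM,
         "d_prox_mm": d["portal_vein"], "d_dist_mm": d["portal_vein"],
         "nodes": ["n_bif", "n_ref"]},
    ]
    faces = [
        {"id": "f_splenic", "node": "n_sv", "diameter_mm": d["splenic"], "role": "inlet"},
        {"id": "f_superior_mesenteric", "node": "n_smv",
         "diameter_mm": d["superior_mesenteric"], "role": "inlet"},
        {"id": "f_inferior_mesenteric", "node": "n_imv",
         "diameter_mm": d["inferior_mesenteric"], "role": "inlet"},
        {"id": "f_left_portal", "node": "n_lpv", "diameter_mm": d["left_portal"], "role": "outlet"},
        {"id": "f_right_portal", "node": "n_rpv", "diameter_mm": d["right_portal"], "role": "outlet"},
        {"id": "f_reference", "node": "n_ref", "diameter_mm": d["portal_vein"],
         "role": "reference_outlet"},
    ]
    return {"segments": segments, "faces": faces}


def canonical_tree(diameters_mm: dict[str, float] | None = None) -> VesselTree:
    """Build the canonical canine template (see :func:`canonical_tree_spec`)."""
    return build_tree(canonical_tree_spec(diameters_mm))


# ---------------------------------------------------------------------------
# Node layout (geometry is for export only; the solver uses lengths/diameters)
# ---------------------------------------------------------------------------

def layout_nodes(tree: VesselTree) -> dict[str, np.ndarray]:
    """Planar layout: BFS from an arbitrary node, branches fan out at fixed
    angles around the incoming direction.  Millimetres, right-handed frame,
    z = 0 everywhere."""
    if not tree.segments:
        return {}
    # prefer to start from the splanchnic side so the trunk runs along +x
    start = tree.segments[0].node_prox
    for name in ("splenic", "portal_vein"):
        try:
            start = tree.segment_by_name(name).node_prox
            break
        except ConfigurationError:
            continue
    pos: dict[str, np.ndarray] = {start: np.zeros(3)}
    incoming: dict[str, np.ndarray] = {start: np.array([1.0, 0.0, 0.0])}
    visited_segs: set[str] = set()
    frontier = [start]
    while frontier:
        node = frontier.pop(0)
        nxt = [s for s in tree.segments_at(node) if s.id not in visited_segs]
        m = len(nxt)
        if m == 0:
            continue
        angles = [0.0] if m == 1 else list(np.linspace(-math.pi / 3, math.pi / 3, m))
        d_in = incoming[node]
        for ang, seg in zip(angles, sorted(nxt, key=lambda s: s.id)):
            visited_segs.add(seg.id)
            c, s_ = math.cos(ang), math.sin(ang)
            direction = np.array(
                [c * d_in[0] - s_ * d_in[1], s_ * d_in[0] + c * d_in[1], 0.0]
            )
            other = seg.node_dist if seg.node_prox == node else seg.node_prox
            if other not in pos:
                pos[other] = pos[node] + direction * seg.length_mm
                incoming[other] = direction
                frontier.append(other)
    return pos


# ---------------------------------------------------------------------------
# Surface meshing
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Indexed triangle mesh (vertices in mm)."""

    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int

    def edge_lengths(self) -> np.ndarray:
        v, t = self.vertices, self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        return np.linalg.norm(v[e[:, 0]] - v[e[:, 1]], axis=1)

    def triangle_areas(self) -> np.ndarray:
        v, t = self.vertices, self.triangles
        a = v[t[:, 1]] - v[t[:, 0]]
        b = v[t[:, 2]] - v[t[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def edge_face_counts(self) -> dict[tuple[int, int], int]:
        counts: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for i, j in ((0, 1), (1, 2), (2, 0)):
                key = (min(tri[i], tri[j]), max(tri[i], tri[j]))
                counts[key] = counts.get(key, 0) + 1
        return {(int(a), int(b)): c for (a, b), c in counts.items()}


def _orthonormal_basis(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(w, helper)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def _capped_tube(
    p0: np.ndarray, p1: np.ndarray, r0: float, r1: float, target: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed (watertight) triangulated tube with linearly tapered radius."""
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    w = axis / length
    u, v = _orthonormal_basis(w)
    r_mean = 0.5 * (r0 + r1)
    n_theta = max(8, int(round(2.0 * math.pi * r_mean / target)))
    n_ax = max(1, int(round(length / target)))
    theta = 2.0 * math.pi * np.arange(n_theta) / n_theta
    ring_dirs = np.outer(np.cos(theta), u) + np.outer(np.sin(theta), v)

    verts: list[np.ndarray] = []
    tris: list[tuple[int, int, int]] = []

    ring_idx: list[np.ndarray] = []
    for i in range(n_ax + 1):
        t = i / n_ax
        c = p0 + t * axis
        r = r0 + t * (r1 - r0)
        base = len(verts)
        verts.extend(c + r * ring_dirs)
        ring_idx.append(np.arange(base, base + n_theta))

    for i in range(n_ax):
        a, b = ring_idx[i], ring_idx[i + 1]
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            tris.append((a[k], a[k2], b[k2]))
            tris.append((a[k], b[k2], b[k]))

    def _cap(rim: np.ndarray, centre: np.ndarray, radius: float, outward_positive: bool):
        # concentric rings stepping inward by ~target, fan at the middle
        radii = [radius]
        while radii[-1] - target > 0.75 * target:
            radii.append(radii[-1] - target)
        rings = [rim]
        for r in radii[1:]:
            base = len(verts)
            verts.extend(centre + r * ring_dirs)
            rings.append(np.arange(base, base + n_theta))
        for outer, inner in zip(rings[:-1], rings[1:]):
            for k in range(n_theta):
                k2 = (k + 1) % n_theta
                if outward_positive:
                    tris.append((outer[k], outer[k2], inner[k2]))
                    tris.append((outer[k], inner[k2], inner[k]))
                else:
                    tris.append((outer[k2], outer[k], inner[k]))
                    tris.append((outer[k2], inner[k], inner[k2]))
        ci = len(verts)
        verts.append(centre.copy())
        last = rings[-1]
        for k in range(n_theta):
            k2 = (k + 1) % n_theta
            if outward_positive:
                tris.append((ci, last[k], last[k2]))
            else:
                tris.append((ci, last[k2], last[k]))

    _cap(ring_idx[-1], p1, r1, outward_positive=True)   # distal cap, normal +w
    _cap(ring_idx[0], p0, r0, outward_positive=False)   # proximal cap, normal -w
    return np.asarray(verts, dtype=float), np.asarray(tris, dtype=np.int64)


def tube_surface_mesh(
    tree: VesselTree, target_edge_mm: float = 0.5, *, enforce_band: bool = True
) -> TriMesh:
    """Triangulated capped-tube surface for every segment of the tree.

    ``target_edge_mm`` must lie in the 0.2-1.0 mm surface-grid band unless
    ``enforce_band=False``.  Each segment is meshed as an independently
    closed capsule, so every edge of the result is shared by exactly two
    triangles.
    """
    if enforce_band and not (MESH_EDGE_BAND_MM[0] <= target_edge_mm <= MESH_EDGE_BAND_MM[1]):
        raise ParameterError(
            f"target edge {target_edge_mm} mm outside the surface-grid band "
            f"{MESH_EDGE_BAND_MM}; pass enforce_band=False to override"
        )
    if not (target_edge_mm > 0):
        raise ParameterError("target edge must be > 0")
    violations = validate_tree(tree)
    if violations:
        raise ValidationError("cannot mesh an invalid tree: " + "; ".join(violations))
    pos = layout_nodes(tree)
    all_v: list[np.ndarray] = []
    all_t: list[np.ndarray] = []
    offset = 0
    for seg in tree.segments:
        v, t = _capped_tube(
            pos[seg.node_prox], pos[seg.node_dist],
            0.5 * seg.d_prox_mm, 0.5 * seg.d_dist_mm, target_edge_mm,
        )
        all_v.append(v)
        all_t.append(t + offset)
        offset += len(v)
    return TriMesh(vertices=np.vstack(all_v), triangles=np.vstack(all_t))


# ---------------------------------------------------------------------------
# Mesh I/O: binary STL and legacy-ASCII VTK polydata
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriMesh, path, fmt: str) -> None:
    """Write ``mesh`` as binary ``STL`` or legacy-ASCII ``VTK`` polydata."""
    fmt_u = fmt.upper()
    if fmt_u == "STL":
        _write_stl(mesh, path)
    elif fmt_u == "VTK":
        _write_vtk_polydata(mesh, path)
    else:
        raise ParameterError(f"unknown mesh format {fmt!r}; expected STL or VTK")


def _write_stl(mesh: TriMesh, path) -> None:
    v, t = mesh.vertices, mesh.triangles
    a = v[t[:, 1]] - v[t[:, 0]]
    b = v[t[:, 2]] - v[t[:, 0]]
    n = np.cross(a, b)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    n = n / norm
    with open(path, "wb") as fh:
        fh.write(b"portoflow binary STL".ljust(80, b"\0"))
        fh.write(struct.pack("<I", len(t)))
        for i in range(len(t)):
            fh.write(struct.pack("<3f", *n[i]))
            for j in range(3):
                fh.write(struct.pack("<3f", *v[t[i, j]]))
            fh.write(struct.pack("<H", 0))


def _write_vtk_polydata(mesh: TriMesh, path, point_data: dict[str, np.ndarray] | None = None) -> None:
    v, t = mesh.vertices, mesh.triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nportoflow surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(t)} {4 * len(t)}\n")
        for tri in t:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for x in arr:
                    fh.write(f"{float(x):.9g}\n")


def read_vtk_polydata(path) -> TriMesh:
    """Minimal reader for the legacy-ASCII polydata this package writes
    (round-trip checks and quick inspection)."""
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("POINTS")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    j = tokens.index("POLYGONS")
    n_poly = int(tokens[j + 1])
    body = np.array(tokens[j + 3 : j + 3 + 4 * n_poly], dtype=np.int64).reshape(n_poly, 4)
    if not np.all(body[:, 0] == 3):
        raise ValidationError("non-triangular polygon in VTK polydata")
    return TriMesh(vertices=coords, triangles=body[:, 1:])
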