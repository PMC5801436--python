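"""Voxelized multi-layer spheres and regular hexahedral meshes.

The head is modeled as nested spherical compartments (brain, CSF, skull,
skin), each with an outer radius and a scalar conductivity.  A segmentation
labels the voxels of a regular grid by the innermost compartment whose outer
radius contains the voxel center; a hexahedral mesh is built with one cube
element per labeled voxel, with exact vertex deduplication on the integer
lattice.  The internal skeleton (faces shared by two elements) carries the
discontinuous-Galerkin coupling terms and the conservative flux degrees of
freedom.

All geometry is stored in meters.  The grid is symmetric about the sphere
center with voxel centers at half-integer multiples of the resolution; this
convention reproduces the reference vertex/element counts of the standard
four-layer validation spheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from ._reference import NODE_OFFSETS
from .errors import InvalidResolutionError

__all__ = [
    "CompartmentSpec",
    "VoxelSegmentation",
    "HexMesh",
    "Skeleton",
    "voxelize_sphere",
    "build_hex_mesh",
    "build_skeleton",
    "find_leaky_points",
    "table1_compartments",
    "four_layer_sphere_mesh",
]

#: Table of the standard four-layer sphere: (name, outer radius [m], sigma [S/m])
_FOUR_LAYER = (
    ("brain", 0.078, 0.33),
    ("csf", 0.080, 1.79),
    ("skull", 0.086, 0.01),
    ("skin", 0.092, 0.43),
)


@dataclass(frozen=True)
class CompartmentSpec:
    """One spherical shell: label name, outer radius [m], conductivity [S/m]."""

    name: str
    outer_radius: float
    conductivity: float

    def __post_init__(self):
        if not self.outer_radius > 0:
            raise ValueError(f"outer_radius must be > 0, got {self.outer_radius}")
        if not self.conductivity > 0:
            raise ValueError(f"conductivity must be > 0, got {self.conductivity}")


@dataclass
class VoxelSegmentation:
    """Integer label grid; 0 marks voxels outside the model.

    ``origin`` is the position of lattice point (0, 0, 0), i.e. the lower
    corner of voxel (0, 0, 0); voxel centers sit at ``origin + (i + 1/2) h``.
    """

    origin: np.ndarray
    voxel_size: float
    labels: np.ndarray  # (nx, ny, nz) int

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    def voxel_centers(self) -> np.ndarray:
        """Centers of all voxels, shape ``dims + (3,)``."""
        h = self.voxel_size
        axes = [self.origin[d] + (np.arange(self.dims[d]) + 0.5) * h for d in range(3)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


@dataclass
class Skeleton:
    """Internal and boundary faces of a regular hexahedral mesh.

    Internal faces are stored once with canonical normal ``+axis`` pointing
    from the lower-index element ``e`` to the higher-index element ``f``.
    ``element_faces[K, 2*axis + side]`` indexes the combined face list
    (internal faces first, then boundary faces) and ``element_face_sign`` is
    +1 where the face's canonical normal is outward for element ``K``.
    """

    face_elems: np.ndarray  # (Fi, 2) int: [e, f]
    face_axis: np.ndarray  # (Fi,) int in {0,1,2}
    face_centroids: np.ndarray  # (Fi, 3)
    bnd_elem: np.ndarray  # (Fb,) int
    bnd_axis: np.ndarray  # (Fb,)
    bnd_side: np.ndarray  # (Fb,) 0 = lower face, 1 = upper face
    bnd_centroids: np.ndarray  # (Fb, 3)
    element_faces: np.ndarray  # (E, 6) int into combined face list
    element_face_sign: np.ndarray  # (E, 6) int8
    area: float

    @property
    def n_internal(self) -> int:
        return len(self.face_axis)

    @property
    def n_boundary(self) -> int:
        return len(self.bnd_axis)

    @property
    def face_normals(self) -> np.ndarray:
        """Canonical unit normals of the internal faces, ``(Fi, 3)``."""
        n = np.zeros((self.n_internal, 3))
        n[np.arange(self.n_internal), self.face_axis] = 1.0
        return n

    @property
    def bnd_normals(self) -> np.ndarray:
        """Outward unit normals of the boundary faces, ``(Fb, 3)``."""
        n = np.zeros((self.n_boundary, 3))
        n[np.arange(self.n_boundary), self.bnd_axis] = np.where(self.bnd_side == 1, 1.0, -1.0)
        return n


@dataclass
class HexMesh:
    """Regular axis-aligned hexahedral mesh with per-element conductivity.

    ``elements[:, i]`` follows the tensor-product corner order
    ``i = a + 2 b + 4 c`` for corner offset ``(a, b, c)``.
    """

    vertices: np.ndarray  # (V, 3) float
    elements: np.ndarray  # (E, 8) int
    element_label: np.ndarray  # (E,) int
    element_sigma: np.ndarray  # (E,) float [S/m]
    h: float
    origin: np.ndarray  # lattice origin [m]
    element_voxel: np.ndarray  # (E, 3) lattice index of the low corner
    compartments: tuple[CompartmentSpec, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_origins(self) -> np.ndarray:
        """Low corner position of every element, ``(E, 3)``."""
        return self.origin[None, :] + self.element_voxel * self.h

    def element_centers(self) -> np.ndarray:
        return self.element_origins() + 0.5 * self.h

    @cached_property
    def _grid(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.element_voxel.min(axis=0)
        hi = self.element_voxel.max(axis=0)
        grid = np.full(tuple(hi - lo + 1), -1, dtype=np.int64)
        g = self.element_voxel - lo
        grid[g[:, 0], g[:, 1], g[:, 2]] = np.arange(self.n_elements)
        return grid, lo

    def locate_element(self, points: np.ndarray) -> np.ndarray:
        """Element id containing each point (half-open ownership [x, x+h)),
        -1 for points outside the mesh."""
        p = np.atleast_2d(points)
        grid, lo = self._grid
        idx = np.floor((p - self.origin) / self.h).astype(np.int64) - lo
        ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
        out = np.full(len(p), -1, dtype=np.int64)
        ii = idx[ok]
        out[ok] = grid[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out if points.ndim > 1 else out  # always 1-D

    def labels_named(self, *names: str) -> np.ndarray:
        """Label values whose compartment name matches one of ``names``."""
        names = tuple(n.lower() for n in names)
        return np.array(
            [k + 1 for k, c in enumerate(self.compartments) if c.name.lower() in names],
            dtype=np.int64,
        )

    @cached_property
    def skeleton(self) -> Skeleton:
        return build_skeleton(self)


def table1_compartments(skull_outer_radius: float = 0.086) -> tuple[CompartmentSpec, ...]:
    """The standard four-layer sphere (radii 78/80/86/92 mm, conductivities
    0.33/1.79/0.01/0.43 S/m).  ``skull_outer_radius`` can be lowered (e.g. to
    82 mm) to create the deliberately leaky thin-skull variant."""
    out = []
    for name, r, s in _FOUR_LAYER:
        if name == "skull":
            r = skull_outer_radius
        out.append(CompartmentSpec(name, r, s))
    return tuple(out)


def voxelize_sphere(
    compartments: list[CompartmentSpec] | tuple[CompartmentSpec, ...],
    resolution: float,
) -> VoxelSegmentation:
    """Label a regular voxel grid by nested spherical compartments.

    A voxel gets the label of the innermost compartment whose outer radius is
    at least the distance of the voxel *center* from the sphere center
    (closed boundary); voxels with center outside the outermost radius get 0.
    The grid is symmetric about the center, voxel centers at (i + 1/2) h.
    """
    comps = tuple(compartments)
    if not comps:
        raise ValueError("need at least one compartment")
    radii = [c.outer_radius for c in comps]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("compartment outer radii must be strictly increasing")
    R = radii[-1]
    if not 0 < resolution < R:
        raise InvalidResolutionError(
            f"resolution {resolution} must lie in (0, outer radius {R})"
        )
    h = float(resolution)
    half = int(np.ceil(R / h + 0.5))
    c = (np.arange(-half, half) + 0.5) * h
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij")
    r = np.sqrt(X * X + Y * Y + Z * Z)
    labels = np.zeros(X.shape, dtype=np.int16)
    for k, rad in enumerate(radii):
        labels[(labels == 0) & (r <= rad)] = k + 1
    origin = np.full(3, -half * h)
    return VoxelSegmentation(origin=origin, voxel_size=h, labels=labels)


def build_hex_mesh(
    seg: VoxelSegmentation,
    compartments: list[CompartmentSpec] | tuple[CompartmentSpec, ...],
) -> HexMesh:
    """One cube element per nonzero voxel, vertices deduplicated exactly by
    integer lattice indexing (no floating-point comparison)."""
    comps = tuple(compartments)
    vox = np.argwhere(seg.labels > 0)
    if len(vox) == 0:
        raise ValueError("segmentation has no labeled voxels")
    labels = seg.labels[seg.labels > 0].astype(np.int64)
    h = seg.voxel_size

    # lattice corner keys: voxel index + corner offset, encoded to one int64
    nx, ny, nz = seg.dims
    corners = vox[:, None, :] + NODE_OFFSETS[None, :, :]  # (E, 8, 3)
    key = (corners[..., 0] * (ny + 2) + corners[..., 1]) * (nz + 2) + corners[..., 2]
    uniq, inverse = np.unique(key.ravel(), return_inverse=True)
    elements = inverse.reshape(len(vox), 8).astype(np.int64)

    # decode unique keys back to lattice coordinates
    vz = uniq % (nz + 2)
    rem = uniq // (nz + 2)
    vy = rem % (ny + 2)
    vx = rem // (ny + 2)
    lattice = np.column_stack([vx, vy, vz])
    vertices = seg.origin[None, :] + lattice * h

    sigma = np.array([c.conductivity for c in comps])[labels - 1]
    return HexMesh(
        vertices=vertices,
        elements=elements,
        element_label=labels,
        element_sigma=sigma,
        h=h,
        origin=np.asarray(seg.origin, dtype=float),
        element_voxel=vox.astype(np.int64),
        compartments=comps,
        metadata={"grid_convention": "center-offset-h/2, closed outer boundary"},
    )


def build_skeleton(mesh: HexMesh) -> Skeleton:
    """Internal faces (each shared by exactly two elements, stored once with
    canonical normal from lower to higher element index) and boundary faces."""
    grid, lo = mesh._grid
    E = mesh.n_elements
    h = mesh.h
    centers = mesh.element_centers()

    element_faces = np.full((E, 6), -1, dtype=np.int64)
    element_face_sign = np.zeros((E, 6), dtype=np.int8)

    fe, fa, fc = [], [], []
    for axis in range(3):
        sl_e = [slice(None)] * 3
        sl_f = [slice(None)] * 3
        sl_e[axis] = slice(0, -1)
        sl_f[axis] = slice(1, None)
        a = grid[tuple(sl_e)].ravel()
        b = grid[tuple(sl_f)].ravel()
        m = (a >= 0) & (b >= 0)
        e, f = a[m], b[m]
        fe.append(np.column_stack([e, f]))
        fa.append(np.full(len(e), axis, dtype=np.int64))
        cent = centers[e]
        cent[:, axis] += 0.5 * h
        fc.append(cent)
    face_elems = np.concatenate(fe)
    face_axis = np.concatenate(fa)
    face_centroids = np.concatenate(fc)
    Fi = len(face_axis)
    fid = np.arange(Fi)
    element_faces[face_elems[:, 0], 2 * face_axis + 1] = fid
    element_face_sign[face_elems[:, 0], 2 * face_axis + 1] = 1
    element_faces[face_elems[:, 1], 2 * face_axis] = fid
    element_face_sign[face_elems[:, 1], 2 * face_axis] = -1

    # remaining element faces are boundary faces with outward normal
    be, ba, bs, bc = [], [], [], []
    for axis in range(3):
        for side in (0, 1):
            slot = 2 * axis + side
            els = np.nonzero(element_faces[:, slot] < 0)[0]
            be.append(els)
            ba.append(np.full(len(els), axis, dtype=np.int64))
            bs.append(np.full(len(els), side, dtype=np.int64))
            cent = centers[els].copy()
            cent[:, axis] += (0.5 if side == 1 else -0.5) * h
            bc.append(cent)
    bnd_elem = np.concatenate(be)
    bnd_axis = np.concatenate(ba)
    bnd_side = np.concatenate(bs)
    bnd_centroids = np.concatenate(bc)
    bid = np.arange(len(bnd_elem))
    element_faces[bnd_elem, 2 * bnd_axis + bnd_side] = Fi + bid
    element_face_sign[bnd_elem, 2 * bnd_axis + bnd_side] = 1

    return Skeleton(
        face_elems=face_elems,
        face_axis=face_axis,
        face_centroids=face_centroids,
        bnd_elem=bnd_elem,
        bnd_axis=bnd_axis,
        bnd_side=bnd_side,
        bnd_centroids=bnd_centroids,
        element_faces=element_faces,
        element_face_sign=element_face_sign,
        area=h * h,
    )


def find_leaky_points(
    mesh: HexMesh,
    skin_names: tuple[str, ...] = ("skin",),
    inner_names: tuple[str, ...] = ("csf", "brain"),
) -> np.ndarray:
    """Vertices incident to at least one skin element AND at least one
    CSF-or-brain element — the spurious single-vertex connections through a
    too-coarse skull layer ("skull leakage")."""
    skin_labels = mesh.labels_named(*skin_names)
    inner_labels = mesh.labels_named(*inner_names)
    skin_verts = np.unique(mesh.elements[np.isin(mesh.element_label, skin_labels)])
    inner_verts = np.unique(mesh.elements[np.isin(mesh.element_label, inner_labels)])
    return np.intersect1d(skin_verts, inner_verts)


def four_layer_sphere_mesh(
    resolution: float,
    skull_outer_radius: float = 0.086,
) -> HexMesh:
    """Convenience: voxelize and mesh the standard four-layer sphere."""
    comps = table1_compartments(skull_outer_radius)
    seg = voxelize_sphere(comps, resolution)
    return build_hex_mesh(seg, comps)
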