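"""Synthetic anatomy: sensor helmets, spherical head models, and source spaces.

All geometry lives in a right-handed RAS head frame (x right, y anterior,
z superior), origin at the single-sphere centre, distances in metres.
Millimetres appear only at reporting surfaces.

The source model mixes two kinds of spaces, mirroring how deep-brain MEG
imaging treats laminar versus non-laminar grey matter:

* surface spaces (neocortex, hippocampus) carry one dipole per vertex,
  oriented along the outward normal — the macrocolumn model;
* volume spaces (amygdala) carry an orthogonal trihedron of dipoles at each
  node of a cubic lattice filling the structure, leaving the net current
  orientation free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .errors import (
    DegenerateFitError,
    EmptySourceSpaceError,
    InvalidConfigError,
)

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Default helmet / conductor geometry (metres).  CTF-style axial gradiometer
#: helmet: scalp sphere 9 cm, inner coils at 11 cm, 5 cm baseline.
DEFAULT_SCALP_RADIUS = 0.09
DEFAULT_HELMET_RADIUS = 0.11
DEFAULT_BASELINE = 0.05
DEFAULT_N_CHANNELS = 151
DEFAULT_CAP_ANGLE = np.deg2rad(115.0)

#: Default amygdala ellipsoids: centres (±22, −4, −18) mm, semi-axes chosen to
#: give a volume of ≈ 2 cm³; cubic lattice step 1.8 mm.
DEFAULT_AMYGDALA_CENTERS = {
    "right": np.array([0.022, -0.004, -0.018]),
    "left": np.array([-0.022, -0.004, -0.018]),
}
DEFAULT_AMYGDALA_SEMI_AXES = np.array([0.0098, 0.0074, 0.0070])
DEFAULT_AMYGDALA_SPACING = 0.0018

#: Default hippocampus shells: elongated ellipsoid surfaces posterior-medial
#: to the amygdalae.
DEFAULT_HIPPOCAMPUS_CENTERS = {
    "right": np.array([0.028, -0.022, -0.018]),
    "left": np.array([-0.028, -0.022, -0.018]),
}
DEFAULT_HIPPOCAMPUS_SEMI_AXES = np.array([0.008, 0.022, 0.008])

#: Default hemispheric cortical shells (centre offset and semi-axes).
CORTEX_HEMI_OFFSET = np.array([0.033, 0.0, 0.02])
CORTEX_SEMI_AXES = np.array([0.032, 0.070, 0.055])


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SensorArray:
    """Axial-gradiometer helmet.

    Each channel is a pair of coaxial point coils: the inner coil at
    ``inner_coil_position`` and an outer coil offset by ``baseline_length``
    along the (unit, outward) ``coil_orientation``.
    """

    channel_id: list[str]
    inner_coil_position: np.ndarray  # (n, 3) metres
    coil_orientation: np.ndarray  # (n, 3) unit vectors
    baseline_length: float  # metres

    def __post_init__(self) -> None:
        self.inner_coil_position = np.asarray(self.inner_coil_position, float)
        self.coil_orientation = np.asarray(self.coil_orientation, float)
        norms = np.linalg.norm(self.coil_orientation, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-10:
            raise InvalidConfigError("coil orientations must be unit vectors")
        if len(self.channel_id) != len(self.inner_coil_position):
            raise InvalidConfigError("channel_id / position length mismatch")

    @property
    def n_channels(self) -> int:
        return len(self.channel_id)

    @property
    def outer_coil_position(self) -> np.ndarray:
        return self.inner_coil_position + self.baseline_length * self.coil_orientation


@dataclass
class HeadModel:
    """Spherically symmetric conductor(s).

    ``single_sphere`` shares one centre/radius across channels;
    ``overlapping_spheres`` fits one sphere per channel.  Per-channel arrays
    are stored in both modes so the forward model has a uniform interface.
    """

    mode: str  # {"single_sphere", "overlapping_spheres"}
    sphere_center: np.ndarray  # (n_channels, 3) metres
    sphere_radius: np.ndarray  # (n_channels,) metres

    def __post_init__(self) -> None:
        self.sphere_center = np.atleast_2d(np.asarray(self.sphere_center, float))
        self.sphere_radius = np.atleast_1d(np.asarray(self.sphere_radius, float))
        if np.any(self.sphere_radius <= 0):
            raise InvalidConfigError("sphere radii must be positive")
        if self.mode not in ("single_sphere", "overlapping_spheres"):
            raise InvalidConfigError(f"unknown head-model mode {self.mode!r}")
        if self.mode == "single_sphere":
            if not (
                np.all(self.sphere_center == self.sphere_center[0])
                and np.all(self.sphere_radius == self.sphere_radius[0])
            ):
                raise InvalidConfigError(
                    "single_sphere mode requires identical per-channel spheres"
                )


@dataclass
class SurfaceSourceSpace:
    """Tessellated surface with one normally-oriented dipole per vertex."""

    vertices: np.ndarray  # (n, 3) metres
    triangles: np.ndarray  # (m, 3) int
    normals: np.ndarray  # (n, 3) unit, outward
    structure_label: str  # {"neocortex", "hippocampus"}
    hemisphere: np.ndarray  # (n,) of {"left", "right"}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, int)
        self.normals = np.asarray(self.normals, float)
        self.hemisphere = np.asarray(self.hemisphere)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise InvalidConfigError("triangle indices out of range")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-10:
            raise InvalidConfigError("vertex normals must be unit vectors")

    @property
    def n_sources(self) -> int:
        return len(self.vertices)

    @property
    def n_orientations(self) -> int:
        return 1

    @property
    def positions(self) -> np.ndarray:
        return self.vertices


@dataclass
class VolumeSourceSpace:
    """Cubic lattice of orientation-free (trihedral) dipoles."""

    nodes: np.ndarray  # (n, 3) metres
    spacing: float  # metres
    structure_label: str  # "amygdala"
    hemisphere: np.ndarray  # (n,) of {"left", "right"}
    frames: np.ndarray  # (n, 3, 3); frames[i, j] is unit axis e_{j+1} of node i
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.frames = np.asarray(self.frames, float)
        self.hemisphere = np.asarray(self.hemisphere)
        if len(self.nodes) == 0:
            raise EmptySourceSpaceError("volume source space has no nodes")
        gram = np.einsum("nij,nkj->nik", self.frames, self.frames)
        eye = np.eye(3)
        if np.max(np.abs(gram - eye)) > 1e-10:
            raise InvalidConfigError("trihedral frames must be orthonormal")

    @property
    def n_sources(self) -> int:
        return len(self.nodes)

    @property
    def n_orientations(self) -> int:
        return 3

    @property
    def positions(self) -> np.ndarray:
        return self.nodes


# ---------------------------------------------------------------------------
# sensor array


def build_sensor_array(
    n_channels: int = DEFAULT_N_CHANNELS,
    helmet_radius: float = DEFAULT_HELMET_RADIUS,
    cap_angle: float = DEFAULT_CAP_ANGLE,
    baseline_length: float = DEFAULT_BASELINE,
    center: np.ndarray | None = None,
) -> SensorArray:
    """Quasi-uniform axial-gradiometer helmet on a spherical cap.

    Channels are placed on the cap of half-angle ``cap_angle`` around +z by
    the Fibonacci-lattice rule (deterministic), with radially outward coil
    orientations.  ``n_channels=1`` with a zero cap collapses to a single
    channel at the helmet apex.
    """
    if n_channels < 1:
        raise InvalidConfigError("channel count must be >= 1")
    if baseline_length <= 0:
        raise InvalidConfigError("gradiometer baseline must be positive")
    if helmet_radius <= 0:
        raise InvalidConfigError("helmet radius must be positive")
    center = np.zeros(3) if center is None else np.asarray(center, float)

    i = np.arange(n_channels)
    # uniform in cos(theta) over [cos(cap_angle), 1] -> equal-area placement
    cos_theta = 1.0 - (1.0 - np.cos(cap_angle)) * (i + 0.5) / n_channels
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    phi = i * GOLDEN_ANGLE
    directions = np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    positions = center + helmet_radius * directions
    ids = [f"MEG{k:03d}" for k in range(1, n_channels + 1)]
    return SensorArray(ids, positions, directions, baseline_length)


def sensor_array_to_tsv(array: SensorArray, path) -> None:
    """Write the helmet as TSV (channel_id, x, y, z, ox, oy, oz, baseline)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "channel_id": array.channel_id,
            "x": array.inner_coil_position[:, 0],
            "y": array.inner_coil_position[:, 1],
            "z": array.inner_coil_position[:, 2],
            "ox": array.coil_orientation[:, 0],
            "oy": array.coil_orientation[:, 1],
            "oz": array.coil_orientation[:, 2],
            "baseline": array.baseline_length,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def sensor_array_from_tsv(path) -> SensorArray:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return SensorArray(
        list(df["channel_id"].astype(str)),
        df[["x", "y", "z"]].to_numpy(float),
        df[["ox", "oy", "oz"]].to_numpy(float),
        float(df["baseline"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# meshes


def icosahedron(radius: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Regular icosahedron: 12 vertices, 20 triangles."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        float,
    )
    verts *= radius / np.linalg.norm(verts[0])
    tris = _hull_triangles(verts)
    return verts, tris


def fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic quasi-uniform point set on the full sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    phi = i * GOLDEN_ANGLE
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return radius * pts


def _hull_triangles(points: np.ndarray) -> np.ndarray:
    """Convex-hull triangulation, faces oriented outward from the centroid."""
    hull = ConvexHull(points)
    tris = hull.simplices.copy()
    centroid = points.mean(axis=0)
    v0, v1, v2 = (points[tris[:, k]] for k in range(3))
    face_normals = np.cross(v1 - v0, v2 - v0)
    outward = np.einsum("ij,ij->i", face_normals, v0 - centroid) > 0
    tris[~outward] = tris[~outward][:, [0, 2, 1]]
    return tris


def vertex_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Area-weighted outward vertex normals of a consistently oriented mesh."""
    v0, v1, v2 = (vertices[triangles[:, k]] for k in range(3))
    face_n = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * area
    normals = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(normals, triangles[:, k], face_n)
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    lengths[lengths == 0] = 1.0
    return normals / lengths


def _ellipsoid_shell(
    n_vertices: int,
    center: np.ndarray,
    semi_axes: np.ndarray,
    structure_label: str,
    hemisphere: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed ellipsoidal shell with exactly ``n_vertices`` vertices."""
    if n_vertices == 12:
        unit, tris = icosahedron()
    else:
        unit = fibonacci_sphere(n_vertices)
        tris = _hull_triangles(unit)
    verts = center + unit * semi_axes
    normals = vertex_normals(verts, tris)
    return verts, tris, normals


def build_template_cortex(
    n_vertices: int = 15000,
    head_radius: float = DEFAULT_SCALP_RADIUS,
) -> SurfaceSourceSpace:
    """Two-hemisphere template cortex with exactly ``n_vertices`` vertices.

    Each hemisphere is a closed deformed spherical shell (Fibonacci point set
    triangulated by its convex hull), scaled so the whole surface sits inside
    the scalp sphere.  The achieved vertex count equals the request (split
    n//2 left, the remainder right) and is recorded in ``metadata``.
    """
    if head_radius <= 0:
        raise InvalidConfigError("head radius must be positive")
    if n_vertices < 12:
        raise InvalidConfigError("need at least 12 vertices (6 per hemisphere)")
    scale = head_radius / DEFAULT_SCALP_RADIUS
    n_left = n_vertices // 2
    n_right = n_vertices - n_left
    parts = []
    for hemi, n_hemi in (("left", n_left), ("right", n_right)):
        sign = -1.0 if hemi == "left" else 1.0
        center = scale * CORTEX_HEMI_OFFSET * np.array([sign, 1.0, 1.0])
        parts.append(
            _ellipsoid_shell(n_hemi, center, scale * CORTEX_SEMI_AXES, "neocortex", hemi)
        )
    verts = np.vstack([parts[0][0], parts[1][0]])
    tris = np.vstack([parts[0][1], parts[1][1] + n_left])
    normals = np.vstack([parts[0][2], parts[1][2]])
    hemisphere = np.array(["left"] * n_left + ["right"] * n_right)
    return SurfaceSourceSpace(
        verts,
        tris,
        normals,
        "neocortex",
        hemisphere,
        metadata={"n_vertices": int(len(verts)), "requested": int(n_vertices)},
    )


def build_hippocampus_shell(
    hemisphere: str,
    n_vertices: int = 300,
    center: np.ndarray | None = None,
    semi_axes: np.ndarray | None = None,
) -> SurfaceSourceSpace:
    """Closed hippocampal shell with normally-oriented dipoles."""
    if center is None:
        center = DEFAULT_HIPPOCAMPUS_CENTERS[hemisphere]
    if semi_axes is None:
        semi_axes = DEFAULT_HIPPOCAMPUS_SEMI_AXES
    verts, tris, normals = _ellipsoid_shell(
        n_vertices, np.asarray(center, float), np.asarray(semi_axes, float),
        "hippocampus", hemisphere,
    )
    return SurfaceSourceSpace(
        verts, tris, normals, "hippocampus",
        np.array([hemisphere] * len(verts)),
        metadata={"n_vertices": int(len(verts))},
    )


# ---------------------------------------------------------------------------
# volume grids


@dataclass
class Ellipsoid:
    center: np.ndarray
    semi_axes: np.ndarray

    def contains(self, points: np.ndarray) -> np.ndarray:
        u = (np.asarray(points, float) - self.center) / self.semi_axes
        return np.einsum("...i,...i->...", u, u) <= 1.0

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.center - self.semi_axes, self.center + self.semi_axes


@dataclass
class Box:
    """Axis-aligned box region (useful for lattice-count oracles)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.asarray(self.lower, float)
        self.upper = np.asarray(self.upper, float)
        self.center = 0.5 * (self.lower + self.upper)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, float)
        return np.all((p >= self.lower - 1e-12) & (p <= self.upper + 1e-12), axis=-1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lower, self.upper


def default_amygdala_ellipsoid(hemisphere: str) -> Ellipsoid:
    return Ellipsoid(
        DEFAULT_AMYGDALA_CENTERS[hemisphere].copy(), DEFAULT_AMYGDALA_SEMI_AXES.copy()
    )


def _lattice_points(anchor: np.ndarray, spacing: float, lo: np.ndarray, hi: np.ndarray):
    """Axis-aligned cubic lattice through ``anchor`` covering box [lo, hi]."""
    axes = []
    for d in range(3):
        i_min = int(np.ceil((lo[d] - anchor[d]) / spacing - 1e-12))
        i_max = int(np.floor((hi[d] - anchor[d]) / spacing + 1e-12))
        axes.append(anchor[d] + spacing * np.arange(i_min, i_max + 1))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def build_volume_grid(
    region,
    spacing: float = DEFAULT_AMYGDALA_SPACING,
    structure_label: str = "amygdala",
    hemisphere: str | None = None,
    anchor: np.ndarray | None = None,
) -> VolumeSourceSpace:
    """Cubic lattice of trihedral sources filling a region.

    ``region`` is an :class:`Ellipsoid`, or a ``(mask, affine)`` pair where
    ``mask`` is a boolean 3-D array and ``affine`` the 4×4 voxel-to-world map
    (NIfTI convention).  The lattice is anchored at the region centroid unless
    ``anchor`` is given, so node sets are reproducible bit-exactly.  Frames
    default to the canonical axes.
    """
    if spacing <= 0:
        raise InvalidConfigError("grid spacing must be positive")

    if hasattr(region, "contains") and hasattr(region, "bounds"):
        lo, hi = region.bounds()
        center = getattr(region, "center", 0.5 * (np.asarray(lo) + np.asarray(hi)))
        anchor = center if anchor is None else np.asarray(anchor, float)
        candidates = _lattice_points(anchor, spacing, lo, hi)
        inside = region.contains(candidates)
    else:
        mask, affine = region
        mask = np.asarray(mask, bool)
        idx = np.argwhere(mask)
        if idx.size == 0:
            raise EmptySourceSpaceError("mask has no interior voxels")
        affine = np.asarray(affine, float)
        world = idx @ affine[:3, :3].T + affine[:3, 3]
        lo, hi = world.min(axis=0), world.max(axis=0)
        centroid = world.mean(axis=0)
        anchor = centroid if anchor is None else np.asarray(anchor, float)
        candidates = _lattice_points(anchor, spacing, lo, hi)
        inv = np.linalg.inv(affine)
        vox = candidates @ inv[:3, :3].T + inv[:3, 3]
        ijk = np.rint(vox).astype(int)
        ok = np.all((ijk >= 0) & (ijk < mask.shape), axis=1)
        inside = np.zeros(len(candidates), bool)
        inside[ok] = mask[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
        center = centroid

    nodes = candidates[inside]
    if len(nodes) == 0:
        raise EmptySourceSpaceError("no lattice node falls inside the region")
    if hemisphere is None:
        hemisphere = "right" if center[0] >= 0 else "left"
    frames = np.broadcast_to(np.eye(3), (len(nodes), 3, 3)).copy()
    return VolumeSourceSpace(
        nodes,
        spacing,
        structure_label,
        np.array([hemisphere] * len(nodes)),
        frames,
        metadata={"n_nodes": int(len(nodes))},
    )


def load_mask_nifti(path):
    """Read a binary NIfTI mask; returns ``(mask, affine)`` for build_volume_grid."""
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.get_fdata()) > 0.5, img.affine


# ---------------------------------------------------------------------------
# head-model fitting


def _fit_sphere_lsq(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit: |x - c|^2 = r^2 linearised."""
    pts = np.asarray(points, float)
    if len(pts) < 4 or np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 3:
        raise DegenerateFitError("need >= 4 non-coplanar points for a sphere fit")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("sphere fit collapsed to non-positive radius")
    return center, float(np.sqrt(r2))


def fit_head_model(
    scalp_points: np.ndarray,
    sensors: SensorArray | None = None,
    mode: str = "single_sphere",
    window_deg: float = 60.0,
) -> HeadModel:
    """Fit the spherical conductor model to digitised scalp points.

    ``single_sphere``: one least-squares sphere to all points.
    ``overlapping_spheres``: per channel, a sphere fitted to the scalp points
    within ``window_deg`` of the channel direction (seen from the global
    centre); channels with too few local points fall back to the global fit.
    """
    scalp_points = np.asarray(scalp_points, float)
    center, radius = _fit_sphere_lsq(scalp_points)
    if mode == "single_sphere" or sensors is None:
        n = 1 if sensors is None else sensors.n_channels
        return HeadModel(
            "single_sphere", np.tile(center, (n, 1)), np.full(n, radius)
        )
    if mode != "overlapping_spheres":
        raise InvalidConfigError(f"unknown head-model mode {mode!r}")

    cos_window = np.cos(np.deg2rad(window_deg))
    point_dirs = scalp_points - center
    point_dirs /= np.linalg.norm(point_dirs, axis=1, keepdims=True)
    centers = np.empty((sensors.n_channels, 3))
    radii = np.empty(sensors.n_channels)
    for k in range(sensors.n_channels):
        chan_dir = sensors.inner_coil_position[k] - center
        chan_dir /= np.linalg.norm(chan_dir)
        local = scalp_points[point_dirs @ chan_dir >= cos_window]
        try:
            centers[k], radii[k] = _fit_sphere_lsq(local)
        except DegenerateFitError:
            centers[k], radii[k] = center, radius
    return HeadModel("overlapping_spheres", centers, radii)


# ---------------------------------------------------------------------------
# OBJ mesh IO (via trimesh)


def write_obj(space: SurfaceSourceSpace, path) -> None:
    import trimesh

    mesh = trimesh.Trimesh(
        vertices=space.vertices, faces=space.triangles, process=False
    )
    mesh.export(str(path), file_type="obj")


def read_obj(
    path, structure_label: str = "neocortex", hemisphere_split: float = 0.0
) -> SurfaceSourceSpace:
    """Read a surface mesh; hemispheres assigned by the sign of x."""
    import trimesh

    mesh = trimesh.load(str(path), file_type="obj", process=False)
    verts = np.asarray(mesh.vertices, float)
    tris = np.asarray(mesh.faces, int)
    normals = vertex_normals(verts, tris)
    hemi = np.where(verts[:, 0] < hemisphere_split, "left", "right")
    return SurfaceSourceSpace(verts, tris, normals, structure_label, hemi)


def euler_characteristic(triangles: np.ndarray) -> int:
    """V − E + F of the complex spanned by ``triangles`` (2 for a closed shell)."""
    tris = np.asarray(triangles, int)
    verts = np.unique(tris)
    edges = np.unique(
        np.sort(
            np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]), axis=1
        ),
        axis=0,
    )
    return len(verts) - len(edges) + len(tris)
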