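"""Forward model: dipole fields in a spherical conductor and gain matrices.

The magnetic field of a current dipole inside a spherically symmetric
conductor has the closed form of Sarvas (primary + volume currents):

    B(r) = mu0 / (4 pi F^2) * (F (Q x r0) - ((Q x r0) . r) grad F)

with r0 the dipole location and r the field point, both relative to the
sphere centre, a = r - r0,

    F      = a (r a + r^2 - r0 . r)
    grad F = (a^2/r + (a.r)/a + 2a + 2r) r - (a + 2r + (a.r)/a) r0.

Two classic consequences are used as test oracles elsewhere: radial dipoles
are magnetically silent, and the radial field component equals that of the
free-space (Biot–Savart) dipole field, because volume currents contribute
nothing radial.

An axial gradiometer channel measures the difference of the oriented field
between its two coaxial point coils.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import HeadModel, SensorArray, SurfaceSourceSpace, VolumeSourceSpace
from .errors import AssemblyError, DomainError

MU0_OVER_4PI = 1e-7  # T m / A


def dipole_field(
    position: np.ndarray,
    moment: np.ndarray,
    field_points: np.ndarray,
    sphere_center: np.ndarray | None = None,
    check_domain: bool = True,
) -> np.ndarray:
    """Magnetic field (tesla) of current dipole(s) in a spherical conductor.

    Broadcasts over dipoles and field points: ``position``/``moment`` may be
    (3,) or (n, 3); ``field_points`` may be (3,) or (m, 3).  Returns
    (m, 3) for a single dipole, (n, m, 3) for many.

    ``check_domain`` enforces that field points lie strictly outside the
    sphere through each dipole (the formula's domain of validity).
    """
    center = np.zeros(3) if sphere_center is None else np.asarray(sphere_center, float)
    pos = np.atleast_2d(np.asarray(position, float)) - center  # (n, 3)
    mom = np.atleast_2d(np.asarray(moment, float))  # (n, 3)
    fp = np.atleast_2d(np.asarray(field_points, float)) - center  # (m, 3)
    single_dipole = np.asarray(position).ndim == 1
    single_point = np.asarray(field_points).ndim == 1

    r = fp[None, :, :]  # (1, m, 3)
    r0 = pos[:, None, :]  # (n, 1, 3)
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=-1)  # (n, m)
    rn = np.linalg.norm(r, axis=-1)  # (1, m)
    if check_domain and np.any(rn[0] <= np.linalg.norm(pos, axis=-1)[:, None] + 1e-15):
        raise DomainError("field point inside the conductor sphere of a dipole")

    r0_dot_r = np.einsum("nij,nij->ni", np.broadcast_arrays(r0, r)[0], np.broadcast_arrays(r0, r)[1])
    a_dot_r = np.einsum("nmi,nmi->nm", a_vec, np.broadcast_to(r, a_vec.shape))
    F = a * (rn * a + rn**2 - r0_dot_r)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef_r = a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn
        coef_r0 = a + 2.0 * rn + a_dot_r / a
    gradF = coef_r[..., None] * r - coef_r0[..., None] * r0

    QxR0 = np.cross(mom, pos)[:, None, :]  # (n, 1, 3)
    Q_dot = np.einsum("nmi,nmi->nm", np.broadcast_to(QxR0, gradF.shape), np.broadcast_to(r, gradF.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        B = MU0_OVER_4PI / F[..., None] ** 2 * (
            F[..., None] * QxR0 - Q_dot[..., None] * gradF
        )
    # a dipole at the sphere centre (or with Q x r0 = 0) is silent; F stays
    # finite there but the cross term vanishes identically
    B = np.where(np.isfinite(B), B, 0.0)

    if single_dipole:
        B = B[0]
        return B[0] if single_point else B
    return B[:, 0] if single_point else B


def channel_response(
    position: np.ndarray,
    moment: np.ndarray,
    sensors: SensorArray,
    head_model: HeadModel,
) -> np.ndarray:
    """Axial-gradiometer responses (tesla) of all channels to dipole(s).

    response = B(inner) . orientation - B(outer) . orientation, each channel
    using its own conductor sphere in overlapping mode.
    """
    pos = np.atleast_2d(np.asarray(position, float))
    mom = np.atleast_2d(np.asarray(moment, float))
    n_dip = len(pos)
    out = np.zeros((n_dip, sensors.n_channels))
    inner = sensors.inner_coil_position
    outer = sensors.outer_coil_position
    orient = sensors.coil_orientation

    centers = head_model.sphere_center
    if len(centers) == 1 or np.all(centers == centers[0]):
        c = centers[0]
        B_in = dipole_field(pos, mom, inner, c)  # (n_dip, n_chan, 3)
        B_out = dipole_field(pos, mom, outer, c)
        out = np.einsum("nmi,mi->nm", B_in - B_out, orient)
    else:
        for k in range(sensors.n_channels):
            c = centers[k]
            B_in = dipole_field(pos, mom, inner[k], c)
            B_out = dipole_field(pos, mom, outer[k], c)
            out[:, k] = (B_in - B_out) @ orient[k]
    return out[0] if np.asarray(position).ndim == 1 else out


@dataclass
class GainMatrix:
    """Concatenated lead fields: channels × source components (T per A·m).

    ``component_index`` records, per column, the contributing structure,
    source id within its space, orientation id (``fixed`` for surface
    dipoles, ``e1``/``e2``/``e3`` for trihedral nodes), and hemisphere.
    """

    values: np.ndarray  # (n_channels, n_components)
    component_index: list[tuple[str, int, str, str]]
    sensor_ref: str = "sensors"
    sourcespace_ref: str = "sources"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape[1] != len(self.component_index):
            raise AssemblyError("component index length != gain column count")
        if not np.all(np.isfinite(self.values)):
            raise AssemblyError("gain matrix has non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def columns_of(self, structure_label: str, hemisphere: str | None = None):
        """Column indices of one structure (optionally one hemisphere)."""
        return np.array(
            [
                j
                for j, (lab, _i, _o, hemi) in enumerate(self.component_index)
                if lab == structure_label and (hemisphere is None or hemi == hemisphere)
            ],
            int,
        )


def assemble_gain(
    source_spaces: list,
    sensors: SensorArray,
    head_model: HeadModel,
) -> GainMatrix:
    """Per-structure lead fields, concatenated in input order.

    Surface spaces contribute one column per vertex (unit dipole along the
    vertex normal); volume spaces contribute three columns per node (unit
    dipoles along the trihedral frame axes e1, e2, e3).
    """
    if not source_spaces:
        raise AssemblyError("need at least one source space")
    blocks = []
    index: list[tuple[str, int, str, str]] = []
    for space in source_spaces:
        if space.n_sources == 0:
            raise AssemblyError("empty source space in assembly")
        if isinstance(space, SurfaceSourceSpace):
            resp = channel_response(space.vertices, space.normals, sensors, head_model)
            blocks.append(resp.T)  # (n_chan, n_vertices)
            index.extend(
                (space.structure_label, i, "fixed", str(space.hemisphere[i]))
                for i in range(space.n_sources)
            )
        elif isinstance(space, VolumeSourceSpace):
            cols = np.empty((sensors.n_channels, 3 * space.n_sources))
            for axis in range(3):
                resp = channel_response(
                    space.nodes, space.frames[:, axis, :], sensors, head_model
                )
                cols[:, axis::3] = resp.T
            blocks.append(cols)
            for i in range(space.n_sources):
                hemi = str(space.hemisphere[i])
                index.extend(
                    (space.structure_label, i, f"e{axis + 1}", hemi)
                    for axis in range(3)
                )
        else:
            raise AssemblyError(f"unsupported source space type {type(space)!r}")
    values = np.hstack(blocks)
    return GainMatrix(values, index)


# ---------------------------------------------------------------------------
# HDF5 container


def save_gain(gain: GainMatrix, path) -> None:
    """Write the gain and its component index to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=gain.values)
        idx = np.array(
            [(lab, i, ori, hemi) for lab, i, ori, hemi in gain.component_index],
            dtype=[("structure", "S32"), ("source", "i8"), ("orientation", "S8"), ("hemisphere", "S8")],
        )
        f.create_dataset("component_index", data=idx)
        f.attrs["sensor_ref"] = gain.sensor_ref
        f.attrs["sourcespace_ref"] = gain.sourcespace_ref


def load_gain(path) -> GainMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][()]
        idx = f["component_index"][()]
        index = [
            (
                row["structure"].decode(),
                int(row["source"]),
                row["orientation"].decode(),
                row["hemisphere"].decode(),
            )
            for row in idx
        ]
        return GainMatrix(
            values,
            index,
            sensor_ref=str(f.attrs.get("sensor_ref", "sensors")),
            sourcespace_ref=str(f.attrs.get("sourcespace_ref", "sources")),
        )
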