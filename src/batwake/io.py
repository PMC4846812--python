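"""Container formats, configuration and tabular output.

Frame sequences travel in an HDF5 container::

    /frames/u, /frames/v, /frames/w   (t, ny, nz) float64
    /frames/mask                      (t, ny, nz) uint8
    /frames/time                      (t,) float64
    /grid/y, /grid/z                  (ny,), (nz,) float64, m
    /meta                             attributes (U, f_L, rho, mass, ...)

Volumes and scalar fields export to legacy ASCII VTK structured points for
standard 3-D viewers; force and structure tables are CSV via pandas; run
configuration is a plain-text key-value (YAML) file whose defaults are the
acquisition constants this package targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import ScalarField3D, SchemaError, SequenceMeta, VectorFieldFrame, WakeVolume
from .forces import ForceRecord
from .structures import VortexStructure
from .synthetic import FilamentWake, _projected_area_z

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_frames",
    "write_frames",
    "export_vtk",
    "read_vtk",
    "forces_to_csv",
    "structures_to_csv",
    "truth_to_csv",
]

_META_FIELDS = ("U", "f_L", "rho", "mass", "sheet_distance")


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run (defaults: acquisition values)."""

    scenario: str = "cruise_wingbeat"
    U: float = 4.0
    f_L: float = 640.0
    rho: float = 1.2
    mass: float = 0.009
    sheet_distance: float = 0.10
    spacing: float = 0.0024
    q_threshold: float = 2500.0
    q_threshold_body: float = 2000.0
    outlier_k: float = 2.0
    smooth_sigma: float = 0.65
    smooth_kernel: int = 5
    min_size: int = 8
    tolerance: float = 0.20
    seed: int = 0
    noise_sd_fraction: float = 0.01  # velocity noise sd as a fraction of U
    spurious_fraction: float = 0.02
    dropout_fraction: float = 0.0
    cull_distance: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "U", "f_L", "rho", "mass", "sheet_distance", "spacing",
            "q_threshold", "q_threshold_body", "outlier_k", "smooth_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config parameter {name} must be positive")

    def meta(self) -> SequenceMeta:
        return SequenceMeta(
            U=self.U,
            f_L=self.f_L,
            rho=self.rho,
            mass=self.mass,
            sheet_distance=self.sheet_distance,
        )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a key-value config file; keyword arguments override file values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError("config file must contain key: value pairs")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Frame container
# ---------------------------------------------------------------------------

def write_frames(
    path: str | Path, frames: list[VectorFieldFrame], meta: SequenceMeta
) -> None:
    """Write a frame sequence and its metadata to the HDF5 container."""
    if not frames:
        raise ValueError("no frames to write")
    f0 = frames[0]
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("frames")
        for name in ("u", "v", "w"):
            grp.create_dataset(
                name, data=np.stack([getattr(fr, name) for fr in frames])
            )
        grp.create_dataset(
            "mask",
            data=np.stack([fr.valid_mask for fr in frames]).astype(np.uint8),
        )
        grp.create_dataset("time", data=np.array([fr.timestamp for fr in frames]))
        g = fh.create_group("grid")
        g.create_dataset("y", data=f0.y)
        g.create_dataset("z", data=f0.z)
        m = fh.create_group("meta")
        for name in _META_FIELDS:
            m.attrs[name] = getattr(meta, name)
        m.attrs["body_center_y"] = (
            "auto" if meta.body_center_y is None else meta.body_center_y
        )


def read_frames(path: str | Path) -> tuple[list[VectorFieldFrame], SequenceMeta]:
    """Read a frame sequence; raises :class:`SchemaError` naming missing pieces."""
    with h5py.File(path, "r") as fh:
        for ds in ("frames/u", "frames/v", "frames/w", "frames/mask",
                   "frames/time", "grid/y", "grid/z"):
            if ds not in fh:
                raise SchemaError(f"container is missing dataset /{ds}")
        if "meta" not in fh:
            raise SchemaError("container is missing the /meta group")
        u = fh["frames/u"][()]
        v = fh["frames/v"][()]
        w = fh["frames/w"][()]
        mask = fh["frames/mask"][()].astype(bool)
        time = fh["frames/time"][()]
        y = fh["grid/y"][()]
        z = fh["grid/z"][()]
        attrs = dict(fh["meta"].attrs)

    for name, arr in (("u", u), ("v", v), ("w", w), ("mask", mask)):
        if arr.shape != u.shape:
            raise SchemaError(f"/frames/{name} shape {arr.shape} != {u.shape}")
    if u.ndim != 3 or u.shape[1:] != (y.size, z.size):
        raise SchemaError(
            f"/frames arrays of shape {u.shape} do not match grid "
            f"({y.size}, {z.size})"
        )
    if time.shape != (u.shape[0],):
        raise SchemaError("/frames/time length does not match the frame count")
    missing = [k for k in _META_FIELDS if k not in attrs]
    if missing:
        raise SchemaError(f"/meta is missing attributes: {missing}")
    bcy = attrs.get("body_center_y", "auto")
    meta = SequenceMeta(
        **{k: float(attrs[k]) for k in _META_FIELDS},
        body_center_y=None if isinstance(bcy, (str, bytes)) else float(bcy),
    )
    frames = [
        VectorFieldFrame(
            u=u[j], v=v[j], w=w[j], valid_mask=mask[j],
            timestamp=float(time[j]), y=y, z=z,
        )
        for j in range(u.shape[0])
    ]
    return frames, meta


# ---------------------------------------------------------------------------
# VTK structured-points export (legacy ASCII)
# ---------------------------------------------------------------------------

def export_vtk(
    path: str | Path,
    vol: WakeVolume,
    scalars: dict[str, ScalarField3D] | None = None,
    require_isotropic: bool = True,
) -> None:
    """Write the volume (and named scalar fields) as a legacy VTK file.

    The file is ASCII ``STRUCTURED_POINTS`` with a ``velocity`` vector array
    and one scalar array per entry of ``scalars`` (e.g. ``Q``, ``omega_x``,
    ``w``), readable by standard 3-D viewers.
    """
    if require_isotropic and not vol.is_isotropic:
        raise ValueError("export requires an isotropic volume (resample first)")
    scalars = scalars or {}
    for name, field in scalars.items():
        if field.shape != vol.shape:
            raise ValueError(f"scalar field {name!r} shape does not match volume")
    nx, ny, nz = vol.shape
    n = nx * ny * nz

    def flat(a: np.ndarray) -> np.ndarray:
        # VTK structured points run x fastest; our arrays are [ix, iy, iz]
        return a.ravel(order="F")

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("batwake wake volume\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN {:.9g} {:.9g} {:.9g}\n".format(*vol.origin))
        fh.write("SPACING {:.9g} {:.9g} {:.9g}\n".format(*vol.spacing))
        fh.write(f"POINT_DATA {n}\n")
        fh.write("VECTORS velocity double\n")
        uvw = np.column_stack([flat(vol.u), flat(vol.v), flat(vol.w)])
        np.savetxt(fh, uvw, fmt="%.9g")
        for name, field in scalars.items():
            fh.write(f"SCALARS {name} double 1\n")
            fh.write("LOOKUP_TABLE default\n")
            np.savetxt(fh, flat(field.values), fmt="%.9g")


def read_vtk(path: str | Path) -> tuple[WakeVolume, dict[str, ScalarField3D]]:
    """Minimal reader for files produced by :func:`export_vtk` (round-trips)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    dims = origin = spacing = None
    i = 0
    while i < len(lines):
        t = lines[i].split()
        if not t:
            i += 1
            continue
        if t[0] == "DIMENSIONS":
            dims = tuple(int(x) for x in t[1:4])
        elif t[0] == "ORIGIN":
            origin = tuple(float(x) for x in t[1:4])
        elif t[0] == "SPACING":
            spacing = tuple(float(x) for x in t[1:4])
        elif t[0] == "VECTORS":
            break
        i += 1
    if dims is None or origin is None or spacing is None:
        raise SchemaError("not a structured-points file written by export_vtk")
    nx, ny, nz = dims
    n = nx * ny * nz

    def unflat(flatvals: np.ndarray) -> np.ndarray:
        return flatvals.reshape((nx, ny, nz), order="F")

    vec = np.loadtxt(lines[i + 1 : i + 1 + n])
    vol = WakeVolume(
        u=unflat(vec[:, 0]), v=unflat(vec[:, 1]), w=unflat(vec[:, 2]),
        spacing=spacing, origin=origin,
    )
    fields: dict[str, ScalarField3D] = {}
    j = i + 1 + n
    while j < len(lines):
        t = lines[j].split()
        if t and t[0] == "SCALARS":
            name = t[1]
            vals = np.loadtxt(lines[j + 2 : j + 2 + n])
            fields[name] = ScalarField3D(
                values=unflat(vals), spacing=spacing, origin=origin
            )
            j += 2 + n
        else:
            j += 1
    return vol, fields


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def forces_to_csv(record: ForceRecord, path: str | Path) -> pd.DataFrame:
    """Write the momentary-force series with wingbeat assignments as CSV."""
    n = record.momentary_force.size
    wingbeat_id = np.full(n, -1)
    pct = np.full(n, np.nan)
    for k, (a, b) in enumerate(record.wingbeat_bounds):
        wingbeat_id[a:b] = k
        pct[a:b] = record.weight_support_pct[k]
    df = pd.DataFrame(
        {
            "frame": np.arange(n),
            "time": record.time,
            "force_N": record.momentary_force,
            "wingbeat_id": wingbeat_id,
            "weight_support_pct": pct,
            "accepted": record.accepted,
        }
    )
    df.to_csv(path, index=False)
    return df


def structures_to_csv(
    structures: list[VortexStructure], path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "label": s.label,
                "voxels": s.voxel_count,
                "volume_m3": s.volume,
                "centroid_x": s.centroid[0],
                "centroid_y": s.centroid[1],
                "centroid_z": s.centroid[2],
                "mean_w": s.mean_w,
                "circulation": s.circulation,
                "sense": s.sense,
            }
            for s in structures
        ]
    )
    df.to_csv(path, index=False)
    return df


def truth_to_csv(wake: FilamentWake, rho: float, path: str | Path) -> pd.DataFrame:
    """Ground-truth filament table: circulation, core size, loop impulse."""
    rows = []
    for i, fil in enumerate(wake.filaments):
        rows.append(
            {
                "id": i,
                "circulation": fil.circulation,
                "core_radius": fil.core_radius,
                "n_vertices": fil.vertices.shape[0],
                "impulse_Ns": (
                    -rho * fil.circulation * _projected_area_z(fil.vertices)
                    if fil.is_closed
                    else np.nan
                ),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
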