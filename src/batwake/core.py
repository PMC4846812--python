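"""Shared containers and conventions for transverse-plane wake analysis.

Coordinate convention (right-handed, used by every module):

* ``x`` — streamwise, positive downstream (flight direction is ``-x``),
* ``y`` — spanwise, positive to the animal's right (starboard),
* ``z`` — vertical, positive up.

A measurement frame lives on a fixed transverse (y-z) plane; the streamwise
vorticity ``omega_x`` is therefore the component available from in-plane
derivatives and the one that carries the lift signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRAVITY",
    "VectorFieldFrame",
    "SequenceMeta",
    "WakeVolume",
    "ScalarField3D",
    "QualityError",
    "SchemaError",
    "ScenarioError",
    "make_grid",
    "interrogation_spacing",
    "vectors_per_cm",
]

#: Standard gravitational acceleration used to convert force to weight support.
GRAVITY = 9.81  # m/s^2


class QualityError(ValueError):
    """A frame or sequence fails a data-quality gate (e.g. too few valid vectors)."""


class SchemaError(ValueError):
    """A container file does not match the expected layout."""


class ScenarioError(ValueError):
    """Unknown synthetic scenario or non-physical scenario parameters."""


def _uniform_spacing(coords: np.ndarray, name: str) -> float:
    """Return the spacing of a coordinate axis, checking uniformity."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 1 or coords.size < 2:
        raise ValueError(f"{name} must be a 1-D array with at least 2 points")
    steps = np.diff(coords)
    h = float(steps[0])
    if not np.allclose(steps, h, rtol=1e-6, atol=1e-12):
        raise ValueError(f"{name} grid is not uniformly spaced")
    return h


@dataclass
class VectorFieldFrame:
    """One time-stamped transverse-plane grid of three-component velocities.

    Arrays are indexed ``[iy, iz]``: the first axis runs along the spanwise
    coordinate ``y`` and the second along the vertical coordinate ``z``.

    Parameters
    ----------
    u, v, w
        Streamwise, spanwise and vertical velocity components, m/s.
    valid_mask
        Boolean grid; ``False`` marks vectors the acquisition rejected
        (holes to be filled during preprocessing).
    timestamp
        Acquisition time of the frame, s.
    y, z
        Uniform 1-D grid coordinates of the plane, m.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    valid_mask: np.ndarray
    timestamp: float
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        shape = self.u.shape
        for name in ("v", "w", "valid_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != u shape {shape}")
        if shape != (self.y.size, self.z.size):
            raise ValueError(
                f"velocity grids of shape {shape} do not match grid axes "
                f"({self.y.size}, {self.z.size})"
            )
        # validate uniformity once at construction
        _uniform_spacing(self.y, "y")
        _uniform_spacing(self.z, "z")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    def copy(self) -> "VectorFieldFrame":
        return VectorFieldFrame(
            u=self.u.copy(),
            v=self.v.copy(),
            w=self.w.copy(),
            valid_mask=self.valid_mask.copy(),
            timestamp=self.timestamp,
            y=self.y.copy(),
            z=self.z.copy(),
        )


@dataclass
class SequenceMeta:
    """Physical constants and acquisition parameters of a PIV sequence.

    Parameters
    ----------
    U
        Free-stream (tunnel / flight) speed, m/s.
    mass
        Animal mass, kg.
    f_L
        Acquisition frame rate, Hz.
    rho
        Air density, kg/m^3.
    sheet_distance
        Streamwise distance between the animal and the light sheet, m.
    body_center_y
        Spanwise position of the body symmetry plane, m, or ``None`` to
        estimate it automatically from wake antisymmetry.
    """

    U: float
    mass: float = 0.009
    f_L: float = 640.0
    rho: float = 1.2
    sheet_distance: float = 0.10
    body_center_y: float | None = None

    def __post_init__(self) -> None:
        for name in ("U", "f_L", "rho", "mass"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")

    @property
    def frame_spacing(self) -> float:
        """Streamwise distance the frozen wake travels between frames, U/f_L (m)."""
        return self.U / self.f_L

    @property
    def transit_time(self) -> float:
        """Time for the wake to convect from the animal to the light sheet (s)."""
        return self.sheet_distance / self.U

    @property
    def weight(self) -> float:
        """Body weight, N."""
        return self.mass * GRAVITY


@dataclass
class WakeVolume:
    """Pseudo-3D velocity volume built by stacking transverse frames.

    Arrays are indexed ``[ix, iy, iz]`` with axes (x streamwise, y spanwise,
    z vertical); ``spacing`` and ``origin`` fix the voxel geometry.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.u.shape != self.v.shape or self.u.shape != self.w.shape:
            raise ValueError("u, v, w must share one shape")
        if self.u.ndim != 3:
            raise ValueError("volume components must be 3-D arrays")
        if min(self.u.shape) < 2:
            raise ValueError("volume must have at least 2 grid points per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape

    @property
    def is_isotropic(self) -> bool:
        dx, dy, dz = self.spacing
        return np.isclose(dx, dy, rtol=1e-9) and np.isclose(dx, dz, rtol=1e-9)

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    @property
    def x(self) -> np.ndarray:
        return self.axis_coords(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis_coords(1)

    @property
    def z(self) -> np.ndarray:
        return self.axis_coords(2)


@dataclass
class ScalarField3D:
    """Scalar quantity on the grid of a :class:`WakeVolume` (e.g. Q, omega_x)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarField3D requires a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def make_grid(
    width: float = 0.30,
    height: float = 0.20,
    spacing: float = 0.0024,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (y, z) axes of a measurement plane.

    Defaults reproduce the acquisition geometry this package targets: a
    roughly 0.30 m x 0.20 m imaged area at 0.0024 m vector pitch, which gives
    a 126 x 84 vector grid.

    Returns
    -------
    (y, z)
        1-D coordinate arrays, centered on ``center``.
    """
    if spacing <= 0 or width <= 0 or height <= 0:
        raise ValueError("width, height and spacing must be positive")
    ny = int(np.floor(width / spacing + 1e-9)) + 1
    nz = int(np.floor(height / spacing + 1e-9)) + 1
    y = center[0] + spacing * (np.arange(ny) - (ny - 1) / 2)
    z = center[1] + spacing * (np.arange(nz) - (nz - 1) / 2)
    return y, z


def interrogation_spacing(
    pixels_per_cm: float = 65.0, window_px: int = 32, overlap: float = 0.5
) -> float:
    """In-plane vector spacing (m) implied by a PIV interrogation scheme.

    With a final interrogation window of ``window_px`` pixels and fractional
    window ``overlap``, vectors are produced every ``window_px * (1-overlap)``
    pixels; dividing by the image scale gives the physical vector pitch.
    """
    if pixels_per_cm <= 0 or window_px <= 0 or not 0 <= overlap < 1:
        raise ValueError("non-physical interrogation parameters")
    step_px = window_px * (1.0 - overlap)
    return (step_px / pixels_per_cm) / 100.0


def vectors_per_cm(
    pixels_per_cm: float = 65.0, window_px: int = 32, overlap: float = 0.5
) -> float:
    """Vector grid density (vectors per cm) of a PIV interrogation scheme."""
    return 0.01 / interrogation_spacing(pixels_per_cm, window_px, overlap)
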