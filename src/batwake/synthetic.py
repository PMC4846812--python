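"""Ground-truth vortex-filament wakes and PIV-like sampling of them.

The generator represents a wake as a set of closed vortex filaments
(polylines with a circulation and a Lamb-Oseen core radius), computes the
induced velocity with a regularized Biot-Savart law, and samples a fixed
transverse plane while the wake convects rigidly downstream at the tunnel
speed (frozen-flow). Because the filament geometry and circulations are
known, the hydrodynamic impulse of the wake is available in closed form and
serves as the oracle for the force estimator.

Sign conventions follow :mod:`batwake.core`: x downstream, y starboard,
z up. A closed horizontal loop whose circulation induces downwash inside it
(a lift-carrying wake loop) has positive vertical impulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ScenarioError, SequenceMeta, VectorFieldFrame, make_grid

__all__ = [
    "VortexFilament",
    "FilamentWake",
    "NoiseSpec",
    "build_scenario",
    "induced_velocity",
    "sample_plane_sequence",
    "ground_truth_impulse",
    "n_frames_to_clear",
    "SCENARIOS",
]


@dataclass
class VortexFilament:
    """A vortex filament: an ordered 3-D polyline with circulation and core size.

    Parameters
    ----------
    vertices
        ``(n, 3)`` array of points, m. A closed filament repeats its first
        point as its last; otherwise set ``truncated=True`` to flag a
        filament cut at the domain boundary.
    circulation
        Signed circulation, m^2/s, right-hand rule along the vertex order.
    core_radius
        Lamb-Oseen core parameter ``r_c``, m; regularizes the induced
        velocity and sets the peak vorticity ``Gamma / (pi r_c^2)``.
    """

    vertices: np.ndarray
    circulation: float
    core_radius: float
    truncated: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ScenarioError("vertices must be an (n, 3) array")
        if np.unique(self.vertices, axis=0).shape[0] < 3:
            raise ScenarioError("a filament needs at least 3 distinct vertices")
        if not np.isfinite(self.circulation) or self.circulation == 0.0:
            raise ScenarioError("circulation must be finite and nonzero")
        if self.core_radius <= 0:
            raise ScenarioError("core_radius must be positive")
        if not self.truncated and not np.allclose(
            self.vertices[0], self.vertices[-1], atol=1e-12
        ):
            raise ScenarioError(
                "filament is not closed (first point != last point); "
                "flag truncated=True if cut at the boundary"
            )

    @property
    def is_closed(self) -> bool:
        return not self.truncated

    def translated(self, offset: np.ndarray) -> "VortexFilament":
        return VortexFilament(
            self.vertices + np.asarray(offset, dtype=float),
            self.circulation,
            self.core_radius,
            self.truncated,
        )


@dataclass
class FilamentWake:
    """A synthetic wake: vortex filaments in the tunnel-fixed frame.

    ``advection_speed`` is the rigid downstream convection speed of the whole
    wake (the tunnel speed U); self-induced deformation is ignored.
    """

    filaments: list[VortexFilament]
    advection_speed: float

    def __post_init__(self) -> None:
        if not self.filaments:
            raise ScenarioError("wake must contain at least one filament")
        if self.advection_speed <= 0:
            raise ScenarioError("advection_speed must be positive")

    def translated(self, offset) -> "FilamentWake":
        off = np.asarray(offset, dtype=float)
        return FilamentWake(
            [f.translated(off) for f in self.filaments], self.advection_speed
        )

    def bounding_x(self) -> tuple[float, float]:
        xs = np.concatenate([f.vertices[:, 0] for f in self.filaments])
        return float(xs.min()), float(xs.max())

    def scaled_circulation(self, factor: float) -> "FilamentWake":
        return FilamentWake(
            [
                VortexFilament(f.vertices.copy(), f.circulation * factor, f.core_radius, f.truncated)
                for f in self.filaments
            ],
            self.advection_speed,
        )


@dataclass
class NoiseSpec:
    """Measurement imperfections applied when sampling a wake onto a plane.

    ``velocity_noise_sd`` adds i.i.d. Gaussian noise to every component;
    ``spurious_fraction`` replaces a fixed count ``round(f * N)`` of vectors
    with uniform outliers in +/- 5 U; ``dropout_fraction`` masks a fixed
    count of vectors invalid (holes). ``rng_seed`` makes output reproducible.
    """

    velocity_noise_sd: float = 0.0
    spurious_fraction: float = 0.0
    dropout_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.velocity_noise_sd < 0:
            raise ScenarioError("velocity_noise_sd must be >= 0")
        for name in ("spurious_fraction", "dropout_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Biot-Savart induction
# ---------------------------------------------------------------------------

try:  # compiled kernel; the numpy path below is the reference implementation
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _segment_induction_loops(points, a, b, gamma, r_c, out):
    P = points.shape[0]
    S = a.shape[0]
    pref = gamma / (4.0 * np.pi)
    inv_rc2 = 1.0 / (r_c * r_c)
    for s in range(S):
        ax, ay, az = a[s, 0], a[s, 1], a[s, 2]
        bx, by, bz = b[s, 0], b[s, 1], b[s, 2]
        sx, sy, sz = bx - ax, by - ay, bz - az
        seg2 = sx * sx + sy * sy + sz * sz
        if seg2 <= 0.0:
            continue
        for p in range(P):
            r1x = points[p, 0] - ax
            r1y = points[p, 1] - ay
            r1z = points[p, 2] - az
            r2x = points[p, 0] - bx
            r2y = points[p, 1] - by
            r2z = points[p, 2] - bz
            cx = r1y * r2z - r1z * r2y
            cy = r1z * r2x - r1x * r2z
            cz = r1x * r2y - r1y * r2x
            c2 = cx * cx + cy * cy + cz * cz
            if c2 <= 0.0:
                continue
            n1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
            n2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
            dot = r1x * r2x + r1y * r2y + r1z * r2z
            denom = n1 * n2 * (n1 * n2 + dot)
            if denom <= 0.0:
                continue
            d2 = c2 / seg2
            reg = -np.expm1(-d2 * inv_rc2)
            coef = pref * reg * (n1 + n2) / denom
            out[p, 0] += coef * cx
            out[p, 1] += coef * cy
            out[p, 2] += coef * cz
    return out


if _HAVE_NUMBA:
    _segment_induction_compiled = _njit(cache=True, fastmath=True)(
        _segment_induction_loops
    )


def _segment_induction(
    points: np.ndarray, a: np.ndarray, b: np.ndarray, gamma: float, r_c: float
) -> np.ndarray:
    """Velocity induced at ``points`` by straight segments ``a[k] -> b[k]``.

    Uses the standard closed-form kernel for a straight vortex segment,
    multiplied by the Lamb-Oseen regularization factor
    ``1 - exp(-d^2 / r_c^2)`` where ``d`` is the perpendicular distance to
    the segment's carrier line. For an infinite straight filament the sum
    over collinear segments reproduces the Lamb-Oseen tangential profile
    ``Gamma / (2 pi d) * (1 - exp(-d^2/r_c^2))`` exactly.
    """
    # points: (P, 3); a, b: (S, 3) -> result (P, 3)
    r1 = points[:, None, :] - a[None, :, :]  # (P, S, 3)
    r2 = points[:, None, :] - b[None, :, :]
    seg = b - a  # (S, 3)
    n1 = np.linalg.norm(r1, axis=2)
    n2 = np.linalg.norm(r2, axis=2)
    cross = np.cross(r1, r2)
    cross_sq = np.einsum("psk,psk->ps", cross, cross)
    seg_len = np.linalg.norm(seg, axis=1)  # (S,)

    # perpendicular distance to the carrier line of each segment
    with np.errstate(divide="ignore", invalid="ignore"):
        d_sq = cross_sq / np.maximum(seg_len[None, :] ** 2, 1e-300)
    reg = -np.expm1(-d_sq / r_c**2)  # 1 - exp(-d^2/r_c^2)

    dot = np.einsum("psk,psk->ps", r1, r2)
    denom = n1 * n2 * (n1 * n2 + dot)
    # kernel: Gamma/(4 pi) * (n1+n2)/denom * (r1 x r2); singular only on the
    # carrier line, where the regularization factor vanishes faster.
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = (n1 + n2) / denom
    coef = np.where(np.isfinite(coef), coef, 0.0)
    coef = coef * reg * (gamma / (4.0 * np.pi))
    return np.einsum("ps,psk->pk", coef, cross)


def induced_velocity(
    wake: FilamentWake,
    points: np.ndarray,
    chunk: int = 4096,
    cull_distance: float | None = None,
    plane_x: float | None = None,
) -> np.ndarray:
    """Velocity induced by all filaments of ``wake`` at ``points``.

    Parameters
    ----------
    wake
        The filament wake.
    points
        ``(P, 3)`` array of query points, m.
    chunk
        Number of points processed per vectorized block (memory control).
    cull_distance, plane_x
        If both given, segments whose vertices all lie farther than
        ``cull_distance`` from the plane ``x = plane_x`` are skipped. Far
        segments induce only a smooth, nearly uniform field whose in-plane
        derivatives are negligible, so culling is a cheap approximation when
        only vorticity-derived quantities are needed. Default: no culling.

    Returns
    -------
    ``(P, 3)`` array of velocities, m/s.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must be (P, 3)")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    out = np.zeros_like(pts)
    for fil in wake.filaments:
        a = fil.vertices[:-1]
        b = fil.vertices[1:]
        if cull_distance is not None and plane_x is not None:
            keep = (
                np.minimum(np.abs(a[:, 0] - plane_x), np.abs(b[:, 0] - plane_x))
                <= cull_distance
            )
            a, b = a[keep], b[keep]
            if a.size == 0:
                continue
        if _HAVE_NUMBA:
            _segment_induction_compiled(
                pts, np.ascontiguousarray(a), np.ascontiguousarray(b),
                fil.circulation, fil.core_radius, out,
            )
        else:
            for lo in range(0, pts.shape[0], chunk):
                sl = slice(lo, lo + chunk)
                out[sl] += _segment_induction(
                    pts[sl], a, b, fil.circulation, fil.core_radius
                )
    return out


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _circle_loop(
    radius: float,
    gamma: float,
    core_radius: float,
    center=(0.0, 0.0, 0.0),
    n_vertices: int = 128,
) -> VortexFilament:
    """Horizontal circular loop oriented so that gamma > 0 induces downwash inside."""
    if radius <= 0:
        raise ScenarioError("radius must be positive")
    # clockwise when viewed from above (+z): theta decreasing
    theta = -2.0 * np.pi * np.arange(n_vertices + 1) / n_vertices
    cx, cy, cz = center
    verts = np.column_stack(
        [
            cx + radius * np.cos(theta),
            cy + radius * np.sin(theta),
            np.full(n_vertices + 1, cz),
        ]
    )
    verts[-1] = verts[0]
    return VortexFilament(verts, gamma, core_radius)


def _rect_loop(
    x_up: float,
    x_down: float,
    y_left: float,
    y_right: float,
    z: float,
    gamma: float,
    core_radius: float,
    max_seg: float = 0.05,
) -> VortexFilament:
    """Horizontal rectangular loop oriented so gamma > 0 induces downwash inside.

    The right leg (at ``y_right``) runs downstream (+x), which with
    gamma > 0 gives positive streamwise vorticity on the starboard side —
    the signature of a lift-generating trailing pair.
    """
    if x_down <= x_up or y_right <= y_left:
        raise ScenarioError("degenerate rectangle")

    def line(p0, p1):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / max_seg)))
        t = np.linspace(0.0, 1.0, n + 1)[:-1, None]
        return p0 + t * (p1 - p0)

    c = [
        (x_up, y_right, z),
        (x_down, y_right, z),
        (x_down, y_left, z),
        (x_up, y_left, z),
    ]
    verts = np.vstack([line(c[0], c[1]), line(c[1], c[2]), line(c[2], c[3]), line(c[3], c[0]), [c[0]]])
    return VortexFilament(verts, gamma, core_radius)


def _single_ring(params: dict) -> FilamentWake:
    R = params.get("R", 0.1)
    gamma = params.get("gamma", 0.5)
    r_c = params.get("core_radius", 0.015)
    U = params.get("U", 4.0)
    center = params.get("center", (-(R + 6 * r_c), 0.0, 0.0))
    n_vertices = params.get("n_vertices", 128)
    if gamma == 0:
        raise ScenarioError("gamma must be nonzero")
    return FilamentWake([_circle_loop(R, gamma, r_c, center, n_vertices)], U)


def _trailing_pair(params: dict) -> FilamentWake:
    """Two long streamwise counter-rotating filaments, each closed far away.

    Each filament is a long thin rectangle: the near leg sits at
    ``+/- b/2`` around ``center_y`` and the return leg at a large spanwise
    offset outside any realistic measurement window, so the window sees two
    straight counter-rotating trailing vortices with circulations
    ``+gamma`` and ``-gamma``.
    """
    b = params.get("b", 0.2)
    gamma = params.get("gamma", 0.5)
    r_c = params.get("core_radius", 0.02)
    U = params.get("U", 4.0)
    center_y = params.get("center_y", 0.0)
    z = params.get("z", 0.0)
    length = params.get("length", 6.0)
    offset = params.get("return_offset", 1.5)
    if b <= 0:
        raise ScenarioError("separation b must be positive")
    if gamma == 0:
        raise ScenarioError("gamma must be nonzero")
    x_up, x_down = -length / 2, length / 2
    # Straight legs need no subdivision: the segment kernel is exact for any
    # length and the core regularization depends only on the carrier line.
    right_geom = _rect_loop(
        x_up, x_down, center_y + b / 2, center_y + b / 2 + offset, z, 1.0, r_c, max_seg=10.0
    )
    # Reverse the vertex order so the in-window (inner) leg runs downstream:
    # with circulation +gamma this puts omega_x = +gamma on the starboard side.
    right = VortexFilament(right_geom.vertices[::-1].copy(), gamma, r_c)
    # The port filament's in-window leg (its y_right edge) already runs
    # downstream in _rect_loop order; carrying -gamma it mirrors the starboard one.
    left = _rect_loop(
        x_up, x_down, center_y - b / 2 - offset, center_y - b / 2, z, -gamma, r_c, max_seg=10.0
    )
    return FilamentWake([right, left], U)


def _cruise_wingbeat(params: dict) -> FilamentWake:
    """Per-wingbeat tip + root loop pairs convecting past the plane.

    Each wingbeat sheds one lift-carrying tip loop (span ``span``) and one
    weaker counter-rotating root loop (span ``root_span``) inside it,
    mimicking the tip/root vortex pairs of flapping cruise flight. When
    ``gamma`` is omitted the tip circulation is tuned so the wake impulse
    per wingbeat equals ``weight_support_target * m g T`` — a wake that
    exactly supports the animal's weight.
    """
    U = params.get("U", 4.0)
    mass = params.get("mass", 0.009)
    f_wb = params.get("wingbeat_frequency", 11.0)
    n_wb = params.get("n_wingbeats", 2)
    span = params.get("span", 0.22)
    root_span = params.get("root_span", 0.06)
    root_fraction = params.get("root_fraction", 0.3)
    duty = params.get("downstroke_fraction", 0.55)
    r_c = params.get("core_radius", 0.012)
    rho = params.get("rho", 1.2)
    target = params.get("weight_support_target", 1.0)
    center_y = params.get("center_y", 0.0)
    gamma = params.get("gamma")

    if f_wb <= 0 or n_wb < 1:
        raise ScenarioError("need positive wingbeat frequency and >= 1 wingbeat")
    T = 1.0 / f_wb
    lam = U * T  # wingbeat wavelength
    L_d = duty * lam  # streamwise length of the downstroke loop
    area_tip = span * L_d
    area_root = root_span * L_d
    if gamma is None:
        # impulse per wingbeat: rho * (gamma*A_tip - root_fraction*gamma*A_root)
        gamma = target * mass * 9.81 * T / (rho * (area_tip - root_fraction * area_root))
    if gamma == 0:
        raise ScenarioError("gamma must be nonzero")

    filaments: list[VortexFilament] = []
    # cell k occupies wake coordinates x in [-(k+1) lam, -k lam]; the fixed
    # plane sweeps these cells in order as the wake convects. One margin
    # wingbeat on each side keeps the plane inside a wake train throughout.
    for k in range(-1, n_wb + 1):
        x_down = -k * lam
        x_up = x_down - L_d
        filaments.append(
            _rect_loop(
                x_up, x_down, center_y - span / 2, center_y + span / 2, 0.0, gamma, r_c
            )
        )
        filaments.append(
            _rect_loop(
                x_up,
                x_down,
                center_y - root_span / 2,
                center_y + root_span / 2,
                0.0,
                -root_fraction * gamma,
                r_c,
            )
        )
    return FilamentWake(filaments, U)


def _reversed_loop(params: dict) -> FilamentWake:
    """A small loop of reversed circulation above a spanwise start vortex.

    The small loop carries negative circulation (upwash inside — negative
    weight support), sitting above a normal-sense start-vortex loop, the
    configuration shed at the upstroke/downstroke transition.
    """
    gamma = params.get("gamma", -0.1)
    R = params.get("R", 0.04)
    r_c = params.get("core_radius", 0.01)
    U = params.get("U", 2.0)
    z_offset = params.get("z_offset", 0.05)
    start_gamma = params.get("start_gamma", 0.08)
    start_span = params.get("start_span", 0.16)
    start_length = params.get("start_length", 0.05)
    center = np.asarray(params.get("center", (0.0, 0.0, 0.0)), dtype=float)
    if gamma >= 0:
        raise ScenarioError("reversed_loop requires gamma < 0 (upwash inside)")
    loops = [
        _circle_loop(R, gamma, r_c, center + np.array([0.0, 0.0, z_offset])),
        _rect_loop(
            center[0] - start_length / 2,
            center[0] + start_length / 2,
            center[1] - start_span / 2,
            center[1] + start_span / 2,
            center[2],
            start_gamma,
            r_c,
        ),
    ]
    return FilamentWake(loops, U)


def straight_filament_wake(
    gamma: float = 0.5, r_c: float = 0.02, L: float = 200.0, U: float = 4.0
) -> FilamentWake:
    """A single (effectively infinite) straight streamwise filament.

    Calibration object: its tangential velocity and peak vorticity follow
    the Lamb-Oseen closed forms, making it the oracle for vorticity and
    circulation recovery tests.
    """
    verts = np.array([[-L, 0.0, 0.0], [0.0, 0.0, 0.0], [L, 0.0, 0.0]])
    return FilamentWake(
        [VortexFilament(verts, gamma, r_c, truncated=True)], advection_speed=U
    )


SCENARIOS = {
    "single_ring": _single_ring,
    "trailing_pair": _trailing_pair,
    "cruise_wingbeat": _cruise_wingbeat,
    "reversed_loop": _reversed_loop,
}


def build_scenario(name: str, params: dict | None = None) -> FilamentWake:
    """Build a preset ground-truth wake.

    Parameters
    ----------
    name
        One of ``single_ring``, ``trailing_pair``, ``cruise_wingbeat``,
        ``reversed_loop``.
    params
        Scenario parameters (circulation, geometry, U); each preset supplies
        physically plausible defaults.
    """
    if name not in SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    return SCENARIOS[name](dict(params or {}))


# ---------------------------------------------------------------------------
# Plane sampling and ground truth
# ---------------------------------------------------------------------------

def n_frames_to_clear(
    wake: FilamentWake, meta: SequenceMeta, plane_x: float = 0.0, margin: float | None = None
) -> int:
    """Number of frames for the advecting wake to pass fully through the plane."""
    if margin is None:
        margin = 8.0 * max(f.core_radius for f in wake.filaments)
    x_min, _ = wake.bounding_x()
    travel = (plane_x + margin) - x_min
    return max(2, int(np.ceil(travel / meta.frame_spacing)))


def sample_plane_sequence(
    wake: FilamentWake,
    meta: SequenceMeta,
    noise: NoiseSpec | None = None,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    n_frames: int | None = None,
    plane_x: float = 0.0,
    include_freestream: bool = True,
    cull_distance: float | None = None,
) -> list[VectorFieldFrame]:
    """Sample the advecting wake on a fixed transverse plane, frame by frame.

    Frame ``j`` evaluates the induced velocity on the plane grid with the
    wake translated downstream by ``j * U / f_L`` (frozen-flow advection),
    adds the free stream ``U`` to the streamwise component (unless
    ``include_freestream=False``), then applies the requested measurement
    imperfections: Gaussian noise, spurious outlier vectors drawn uniformly
    within +/- 5 U, and masked-out holes.

    Returns a list of :class:`VectorFieldFrame`, timestamped ``j / f_L``.
    """
    noise = noise or NoiseSpec()
    if grid is None:
        grid = make_grid()
    y, z = grid
    if y.size == 0 or z.size == 0:
        raise ValueError("empty grid")
    if meta.f_L <= 0:
        raise ValueError("f_L must be positive")
    if n_frames is None:
        n_frames = n_frames_to_clear(wake, meta, plane_x)
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")

    Y, Z = np.meshgrid(y, z, indexing="ij")
    pts = np.column_stack(
        [np.full(Y.size, plane_x), Y.ravel(), Z.ravel()]
    )
    N = Y.size
    n_spurious = int(round(noise.spurious_fraction * N))
    n_dropout = int(round(noise.dropout_fraction * N))
    amp = 5.0 * abs(meta.U)
    rng = np.random.default_rng(noise.rng_seed)

    dx_frame = meta.frame_spacing
    frames: list[VectorFieldFrame] = []
    for j in range(n_frames):
        shifted = wake.translated((j * dx_frame, 0.0, 0.0))
        vel = induced_velocity(
            shifted, pts, cull_distance=cull_distance, plane_x=plane_x
        )
        u = vel[:, 0].reshape(Y.shape)
        v = vel[:, 1].reshape(Y.shape)
        w = vel[:, 2].reshape(Y.shape)
        if include_freestream:
            u = u + meta.U

        if noise.velocity_noise_sd > 0:
            u = u + rng.normal(0.0, noise.velocity_noise_sd, Y.shape)
            v = v + rng.normal(0.0, noise.velocity_noise_sd, Y.shape)
            w = w + rng.normal(0.0, noise.velocity_noise_sd, Y.shape)
        if n_spurious:
            idx = rng.choice(N, size=n_spurious, replace=False)
            for comp in (u, v, w):
                comp.ravel()[idx] = rng.uniform(-amp, amp, n_spurious)
        mask = np.ones(Y.shape, dtype=bool)
        if n_dropout:
            idx = rng.choice(N, size=n_dropout, replace=False)
            mask.ravel()[idx] = False

        frames.append(
            VectorFieldFrame(
                u=u, v=v, w=w, valid_mask=mask, timestamp=j / meta.f_L, y=y, z=z
            )
        )
    return frames


def _projected_area_z(vertices: np.ndarray) -> float:
    """Signed area of the polygon's horizontal (x-y) projection.

    Shoelace with right-hand orientation about +z: counter-clockwise viewed
    from above is positive.
    """
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def ground_truth_impulse(wake: FilamentWake, rho: float = 1.2) -> float:
    """Vertical hydrodynamic impulse of the wake, N s, positive upward.

    For closed loops the vertical fluid impulse is ``rho Gamma A_z`` with
    ``A_z`` the signed horizontal projected area (right-hand rule about +z).
    The value returned is the lift impulse delivered to the animal, i.e.
    positive when the loop circulation induces downwash inside it.
    """
    total = 0.0
    for fil in wake.filaments:
        if fil.truncated:
            raise ValueError("ground-truth impulse requires closed filaments")
        total += fil.circulation * _projected_area_z(fil.vertices)
    return -rho * total
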