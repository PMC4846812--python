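"""Pseudo-3D wake reconstruction from a transverse-plane frame sequence.

Under the frozen-flow hypothesis the wake convects rigidly past the fixed
measurement plane at the tunnel speed U, so acquisition time maps to
streamwise position: consecutive frames are stacked with an out-of-plane
spacing of ``U / f_L``. The stacked volume is then resampled with cubic
splines to an isotropic grid and smoothed with a small Gaussian kernel
before computing differential quantities.

The stacked representation is a pseudo-volume — a stack of planes each
carrying all three velocity components — not a true instantaneous volume;
the residual error of this approximation is small when wake deformation
between shedding and measurement is dominated by convection.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline

from .core import SequenceMeta, VectorFieldFrame, WakeVolume

__all__ = ["stack_volume", "resample_isotropic", "smooth_gaussian"]


def stack_volume(
    frames: list[VectorFieldFrame], meta: SequenceMeta, flip: bool = False
) -> WakeVolume:
    """Stack repaired frames into a pseudo-3D volume.

    Frames are spaced ``U / f_L`` apart along x. The earliest-acquired
    frame is placed farthest downstream (largest x): wake shed earliest
    crossed the sheet first and has convected farthest by the end of the
    recording. With this ordering the frozen-flow identity
    ``d/dx = -(1/U) d/dt`` holds on the volume grid.

    Parameters
    ----------
    frames
        Repaired frames (full validity mask) on identical grids.
    meta
        Supplies U and f_L.
    flip
        Reverse the x axis (visualization in flight direction).
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to stack a volume")
    f0 = frames[0]
    for fr in frames:
        if fr.shape != f0.shape or not np.allclose(fr.y, f0.y) or not np.allclose(fr.z, f0.z):
            raise ValueError("frames must share one grid")
        if not fr.valid_mask.all():
            raise ValueError("stack_volume requires repaired frames (full valid mask)")
    dz_x = meta.frame_spacing

    order = slice(None, None, -1) if not flip else slice(None)
    u = np.stack([fr.u for fr in frames])[order]
    v = np.stack([fr.v for fr in frames])[order]
    w = np.stack([fr.w for fr in frames])[order]
    return WakeVolume(
        u=u,
        v=v,
        w=w,
        spacing=(dz_x, f0.dy, f0.dz),
        origin=(0.0, float(f0.y[0]), float(f0.z[0])),
    )


def resample_isotropic(vol: WakeVolume, spacing: float = 0.0024) -> WakeVolume:
    """Resample each component onto an isotropic grid with cubic splines.

    The new grid covers the original extent starting at the original origin
    with ``floor(extent / spacing) + 1`` points per axis. Interpolation uses
    prefiltered cubic B-splines, which reproduce polynomials up to degree 3
    exactly in the interior.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    extents = [(n - 1) * s for n, s in zip(vol.shape, vol.spacing)]
    n_new = [int(np.floor(e / spacing + 1e-9)) + 1 for e in extents]
    if min(n_new) < 2:
        raise ValueError("spacing larger than the volume extent")

    src_axes = [s * np.arange(n) for n, s in zip(vol.shape, vol.spacing)]
    new_axes = [spacing * np.arange(n) for n in n_new]
    comps = {}
    for name in ("u", "v", "w"):
        a = getattr(vol, name)
        # separable tricubic: a not-a-knot cubic spline along each axis in turn
        for axis in range(3):
            if a.shape[axis] > 3:
                spl = make_interp_spline(src_axes[axis], a, k=3, axis=axis)
            else:  # too few points for a cubic: degrade gracefully
                spl = make_interp_spline(
                    src_axes[axis], a, k=a.shape[axis] - 1, axis=axis
                )
            a = spl(new_axes[axis])
        comps[name] = a
    return WakeVolume(
        spacing=(spacing, spacing, spacing), origin=vol.origin, **comps
    )


def smooth_gaussian(
    vol: WakeVolume, kernel_size: int = 5, sigma: float = 0.65
) -> WakeVolume:
    """Smooth each component with a truncated Gaussian kernel.

    The kernel is a ``kernel_size^3`` sampled Gaussian of standard deviation
    ``sigma`` voxels, normalized to unit sum (so constant fields pass
    unchanged); boundaries use nearest-edge replication. The 5x5x5 kernel
    with sigma 0.65 matches the common smoothing default applied to stacked
    PIV volumes before vortex identification.
    """
    if kernel_size % 2 != 1 or kernel_size < 1:
        raise ValueError("kernel_size must be odd and positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if any(n < kernel_size for n in vol.shape):
        raise ValueError("kernel larger than the grid")
    half = kernel_size // 2
    x = np.arange(-half, half + 1, dtype=float)
    k1 = np.exp(-(x**2) / (2.0 * sigma**2))
    k1 /= k1.sum()  # separable: product of normalized 1-D kernels has unit sum
    comps = {}
    for name in ("u", "v", "w"):
        a = getattr(vol, name)
        for axis in range(3):
            a = ndimage.correlate1d(a, k1, axis=axis, mode="nearest")
        comps[name] = a
    return WakeVolume(spacing=vol.spacing, origin=vol.origin, **comps)
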