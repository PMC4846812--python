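"""Threshold-based vortex segmentation and per-structure characterization.

Vortex structures are the 26-connected components of ``{Q > threshold}``;
small components are discarded as noise. Each structure is characterized by
its voxel geometry (centroid, volume), the mean vertical induced speed
inside it (upwash vs downwash sense), and the circulation of its dominant
cross-section: the slice, normal to the structure's principal axis, holding
the most member voxels, over which the axis-aligned vorticity component is
integrated (Stokes' theorem). The integration disk is dilated beyond the
thresholded footprint because vortex cores extend below any Q threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ScalarField3D, WakeVolume

__all__ = [
    "VortexStructure",
    "segment_structures",
    "characterize",
    "count_per_interval",
    "color_scale_limit",
]

_CONNECTIVITY = np.ones((3, 3, 3), dtype=int)  # 26-connected


@dataclass
class VortexStructure:
    """One segmented vortex structure (connected region of high Q)."""

    label: int
    voxel_count: int
    volume: float  # m^3
    centroid: tuple[float, float, float]  # m, volume coordinates
    voxels: np.ndarray  # (n, 3) integer indices into the Q grid
    mean_w: float | None = None  # m/s, mean vertical speed inside
    circulation: float | None = None  # m^2/s, dominant cross-section
    sense: str | None = None  # "upwash" | "downwash"


def segment_structures(
    q: ScalarField3D, threshold: float = 2500.0, min_size: int = 8
) -> list[VortexStructure]:
    """Segment vortex structures as 26-connected components of ``Q > threshold``.

    Components smaller than ``min_size`` voxels are discarded; the returned
    list is ordered by descending voxel count and relabeled 1..n. An empty
    list is a valid result.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mask = q.values > threshold
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]  # drop background
    order = np.argsort(counts)[::-1]
    voxel_volume = float(np.prod(q.spacing))
    out: list[VortexStructure] = []
    new_label = 0
    for old in order:
        cnt = int(counts[old])
        if cnt < min_size:
            break  # sorted descending: all remaining are smaller
        new_label += 1
        idx = np.argwhere(labels == old + 1)
        centroid_idx = idx.mean(axis=0)
        centroid = tuple(
            float(q.origin[a] + q.spacing[a] * centroid_idx[a]) for a in range(3)
        )
        out.append(
            VortexStructure(
                label=new_label,
                voxel_count=cnt,
                volume=cnt * voxel_volume,
                centroid=centroid,
                voxels=idx,
            )
        )
    return out


def _vorticity_component(vol: WakeVolume, axis: int) -> np.ndarray:
    """One component of curl(u) on the volume grid."""
    dx, dy, dz = vol.spacing
    if axis == 0:  # omega_x = dw/dy - dv/dz
        return np.gradient(vol.w, dy, axis=1) - np.gradient(vol.v, dz, axis=2)
    if axis == 1:  # omega_y = du/dz - dw/dx
        return np.gradient(vol.u, dz, axis=2) - np.gradient(vol.w, dx, axis=0)
    # omega_z = dv/dx - du/dy
    return np.gradient(vol.v, dx, axis=0) - np.gradient(vol.u, dy, axis=1)


def characterize(
    structure: VortexStructure,
    vol: WakeVolume,
    omega: ScalarField3D | None = None,
    pad_factor: float = 3.0,
) -> VortexStructure:
    """Complete a structure with induced-flow sense and circulation.

    ``mean_w`` averages the vertical velocity over member voxels; ``sense``
    is ``upwash`` when it is positive. The circulation integrates the
    vorticity component along the structure's principal axis over a disk
    centered on the dominant cross-section, with radius ``pad_factor``
    times the footprint's equivalent radius (at least 4 voxels beyond it)
    so the sub-threshold tails of the core are captured.

    ``omega`` (streamwise vorticity) is used directly when the principal
    axis is streamwise; otherwise the needed component is computed from
    ``vol``. Degenerate single-voxel structures get ``circulation=None``.
    """
    if vol.shape != (omega.shape if omega is not None else vol.shape):
        raise ValueError("omega grid does not match the volume")
    idx = structure.voxels
    w_mean = float(vol.w[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
    structure.mean_w = w_mean
    structure.sense = "upwash" if w_mean > 0 else "downwash"

    if idx.shape[0] < 2:
        structure.circulation = None
        return structure
    centered = idx - idx.mean(axis=0)
    cov = centered.T @ centered / idx.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis_vec = evecs[:, -1]  # principal direction of the voxel cloud
    if evals[-1] <= 1e-12:
        structure.circulation = None
        return structure
    slice_axis = int(np.argmax(np.abs(axis_vec)))

    # dominant cross-section: the slice with the most member voxels
    vals, counts = np.unique(idx[:, slice_axis], return_counts=True)
    s = int(vals[np.argmax(counts)])
    in_slice = idx[idx[:, slice_axis] == s]
    plane_axes = [a for a in range(3) if a != slice_axis]
    foot = in_slice[:, plane_axes]
    center = foot.mean(axis=0)
    r_eq = np.sqrt(foot.shape[0] / np.pi)
    radius = max(pad_factor * r_eq, r_eq + 4.0)

    if omega is not None and slice_axis == 0:
        om = omega.values
    else:
        om = _vorticity_component(vol, slice_axis)
    om_slice = np.take(om, s, axis=slice_axis)
    n0, n1 = om_slice.shape
    g0, g1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    disk = (g0 - center[0]) ** 2 + (g1 - center[1]) ** 2 <= radius**2
    h0 = vol.spacing[plane_axes[0]]
    h1 = vol.spacing[plane_axes[1]]
    structure.circulation = float(np.sum(om_slice[disk]) * h0 * h1)
    return structure


def count_per_interval(
    structures: list[VortexStructure],
    intervals: list[tuple[float, float]],
    axis: int = 0,
) -> list[int]:
    """Count structures whose centroid falls in each coordinate interval.

    ``intervals`` are ``[lo, hi)`` ranges along the given volume axis
    (streamwise slabs map to time intervals under frozen flow).
    """
    counts = []
    for lo, hi in intervals:
        counts.append(
            sum(1 for s in structures if lo <= s.centroid[axis] < hi)
        )
    return counts


def color_scale_limit(vol: WakeVolume) -> float:
    """Color-axis limit for vertical-speed maps: mean(|w|) + 3 sd(w), m/s."""
    w = vol.w
    if w.size == 0:
        raise ValueError("empty volume")
    return float(np.mean(np.abs(w)) + 3.0 * np.std(w))
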