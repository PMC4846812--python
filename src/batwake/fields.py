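"""Differential flow quantities: vorticity, velocity gradients, Q-criterion.

All derivatives use second-order central differences (one-sided at the
boundaries), the appropriate order of accuracy for PIV-resolution data.
The Q-criterion,

    Q = 1/2 (||Omega||_F^2 - ||S||_F^2) = -1/2 tr(A^2),

with ``A`` the velocity-gradient tensor and ``S``/``Omega`` its symmetric /
antisymmetric parts, is positive where rotation dominates strain and marks
vortex cores; it is Galilean invariant and is evaluated on the smoothed
isotropic pseudo-volume before thresholding.
"""

from __future__ import annotations

import numpy as np

from .core import ScalarField3D, VectorFieldFrame, WakeVolume

__all__ = [
    "vorticity_x_frame",
    "vorticity_x_volume",
    "velocity_gradient",
    "q_criterion",
]


def vorticity_x_frame(frame: VectorFieldFrame) -> np.ndarray:
    """Streamwise vorticity ``omega_x = dw/dy - dv/dz`` on a frame's grid, 1/s.

    This is the vorticity component recoverable from in-plane derivatives of
    a transverse-plane measurement, and the one whose spanwise first moment
    carries the lift signal.
    """
    ny, nz = frame.shape
    if ny < 3 or nz < 3:
        raise ValueError("grid must be at least 3x3 for central differences")
    dw_dy = np.gradient(frame.w, frame.y, axis=0)
    dv_dz = np.gradient(frame.v, frame.z, axis=1)
    return dw_dy - dv_dz


def vorticity_x_volume(vol: WakeVolume) -> ScalarField3D:
    """Streamwise vorticity on a stacked volume, 1/s."""
    if min(vol.shape[1:]) < 3:
        raise ValueError("y and z axes need at least 3 points")
    dw_dy = np.gradient(vol.w, vol.spacing[1], axis=1)
    dv_dz = np.gradient(vol.v, vol.spacing[2], axis=2)
    return ScalarField3D(
        values=dw_dy - dv_dz, spacing=vol.spacing, origin=vol.origin, units="s^-1"
    )


def velocity_gradient(vol: WakeVolume) -> np.ndarray:
    """Velocity-gradient tensor ``A[i, j] = du_i/dx_j``, shape (3, 3, nx, ny, nz)."""
    if min(vol.shape) < 3:
        raise ValueError("every axis needs at least 3 points for central differences")
    comps = (vol.u, vol.v, vol.w)
    A = np.empty((3, 3) + vol.shape)
    for i, c in enumerate(comps):
        for j in range(3):
            A[i, j] = np.gradient(c, vol.spacing[j], axis=j)
    return A


def q_criterion(vol: WakeVolume) -> ScalarField3D:
    """Q-criterion of the volume, 1/s^2; positive inside vortex cores."""
    A = velocity_gradient(vol)
    # Q = -1/2 tr(A^2) = 1/2 (||Omega||^2 - ||S||^2)
    q = np.zeros(vol.shape)
    for i in range(3):
        for j in range(3):
            q -= 0.5 * A[i, j] * A[j, i]
    return ScalarField3D(values=q, spacing=vol.spacing, origin=vol.origin, units="s^-2")
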