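"""Per-frame PIV vector validation and repair.

Erroneous vectors are detected with a normalized median test on the 3x3
neighborhood: a vector is rejected when any velocity component deviates from
the median of its valid neighbors by more than ``k`` times the neighborhood
residual scale. The residual scale is the median absolute deviation of the
neighbors about their median plus a global noise floor (the frame-wide
median of the local scales), which keeps the test sharp against gross
outliers while preventing false rejections in smooth, low-noise regions.
Detection runs in a single pass; the default multiplier is ``k = 2``.

Rejected vectors are replaced by the median of their valid neighbors, and
remaining holes (masked-out vectors, or rejected vectors with too few valid
neighbors) are filled by linear interpolation from the nearest valid data.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import griddata

from .core import QualityError, VectorFieldFrame

__all__ = ["detect_outliers", "repair", "preprocess_frame", "preprocess_sequence"]

_OFFSETS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def _neighbor_stack(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """(8, ny, nz) stack of neighbor values; invalid/out-of-frame are NaN."""
    ny, nz = values.shape
    padded = np.full((ny + 2, nz + 2), np.nan)
    padded[1:-1, 1:-1] = np.where(valid, values, np.nan)
    stack = np.empty((8, ny, nz))
    for s, (di, dj) in enumerate(_OFFSETS):
        stack[s] = padded[1 + di : 1 + di + ny, 1 + dj : 1 + dj + nz]
    return stack


def detect_outliers(frame: VectorFieldFrame, k: float = 2.0) -> np.ndarray:
    """Flag erroneous vectors with a single-pass normalized median test.

    Parameters
    ----------
    frame
        Input frame; only valid vectors are tested or used as neighbors.
    k
        Rejection multiplier: a component fails when
        ``|value - median(neighbors)| > k * (mad(neighbors) + eps)`` with
        ``eps`` the frame-wide median of the local scales (noise floor).

    Returns
    -------
    Boolean grid of outlier flags (never flags already-invalid vectors).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    ny, nz = frame.shape
    if ny < 3 or nz < 3:
        raise ValueError("frames smaller than 3x3 cannot be validated")

    flags = np.zeros(frame.shape, dtype=bool)
    valid = frame.valid_mask
    for values in (frame.u, frame.v, frame.w):
        stack = _neighbor_stack(values, valid)
        n_valid = np.sum(np.isfinite(stack), axis=0)
        enough = n_valid >= 3
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(stack, axis=0)
            mad = np.nanmedian(np.abs(stack - med), axis=0)
        # consistent robust spread estimate (MAD -> sigma for Gaussian noise)
        scale = 1.4826 * mad
        eps = (
            float(np.nanmedian(scale[enough & valid]))
            if np.any(enough & valid)
            else 0.0
        )
        with np.errstate(invalid="ignore"):
            comp_flags = np.abs(values - med) > k * (scale + eps)
        flags |= comp_flags & valid & enough
    return flags


def _fill_holes(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid cells by linear interpolation from valid data (nearest at edges)."""
    if valid.all():
        return values
    ny, nz = values.shape
    ii, jj = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    pts = np.column_stack([ii[valid], jj[valid]])
    query = np.column_stack([ii[~valid], jj[~valid]])
    filled = values.copy()
    interp = griddata(pts, values[valid], query, method="linear")
    missing = ~np.isfinite(interp)
    if np.any(missing):  # outside the convex hull of valid data
        interp[missing] = griddata(
            pts, values[valid], query[missing], method="nearest"
        )
    filled[~valid] = interp
    return filled


def repair(frame: VectorFieldFrame, flags: np.ndarray) -> VectorFieldFrame:
    """Replace flagged vectors and fill holes; returns a fully valid frame.

    Flagged vectors are replaced by the median of their valid (unflagged)
    3x3 neighbors; masked-out cells and flagged cells with fewer than 3
    valid neighbors are treated as holes and filled by linear interpolation
    from the nearest valid data. Unflagged valid vectors pass through
    bit-exact.

    Raises
    ------
    QualityError
        If fewer than 50% of the vectors are valid and unflagged — the
        frame (and its sequence) should be discarded rather than repaired.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != frame.shape:
        raise ValueError("flags shape does not match frame")
    good = frame.valid_mask & ~flags
    if good.mean() < 0.5:
        raise QualityError(
            f"only {100 * good.mean():.1f}% of vectors are valid; "
            "sequence should be discarded"
        )

    out = frame.copy()
    out.valid_mask = np.ones(frame.shape, dtype=bool)
    for name in ("u", "v", "w"):
        values = getattr(frame, name)
        stack = _neighbor_stack(values, good)
        n_valid = np.sum(np.isfinite(stack), axis=0)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(stack, axis=0)
        replace = flags & (n_valid >= 3)
        result = values.copy()
        result[replace] = med[replace]
        hole = ~good & ~replace
        result = _fill_holes(result, ~hole)
        setattr(out, name, result)
    return out


def preprocess_frame(
    frame: VectorFieldFrame, k: float = 2.0
) -> tuple[VectorFieldFrame, dict]:
    """Detect and repair one frame; returns the repaired frame and counts."""
    flags = detect_outliers(frame, k=k)
    repaired = repair(frame, flags)
    stats = {
        "flagged": int(flags.sum()),
        "holes": int((~frame.valid_mask).sum()),
    }
    return repaired, stats


def preprocess_sequence(
    frames: list[VectorFieldFrame], k: float = 2.0
) -> tuple[list[VectorFieldFrame], list[dict]]:
    """Detect and repair every frame of a sequence."""
    repaired, stats = [], []
    for fr in frames:
        r, s = preprocess_frame(fr, k=k)
        repaired.append(r)
        stats.append(s)
    return repaired, stats
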