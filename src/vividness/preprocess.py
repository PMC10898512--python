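"""Trial-level preprocessing transforms for epoched recordings."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .simulate import EpochedRecording

__all__ = ["baseline_correct", "regress_out_contrast", "smooth_epochs", "boxcar_smooth"]


def baseline_correct(
    rec: EpochedRecording, window_ms: tuple[float, float] = (-200.0, 0.0)
) -> EpochedRecording:
    """Subtract the per-trial per-sensor mean over ``[a, b)`` from the epoch."""
    a, b = window_ms
    sel = (rec.time_ms >= a) & (rec.time_ms < b)
    if not np.any(sel):
        raise ValueError(f"baseline window {window_ms} contains no samples")
    out = rec.copy()
    out.data -= out.data[:, :, sel].mean(axis=2, keepdims=True)
    return out


def regress_out_contrast(rec: EpochedRecording, contrast: np.ndarray) -> EpochedRecording:
    """Remove the across-trial linear contrast component at every (sensor, sample).

    Ordinary least squares of the data on [intercept, contrast]; only the
    contrast component is subtracted, the intercept is retained.  A constant
    contrast carries no across-trial information and the data are returned
    unchanged (degenerate case by convention).
    """
    c = np.asarray(contrast, dtype=float)
    if c.size != rec.n_trials:
        raise ValueError("contrast length must equal trial count")
    out = rec.copy()
    cc = c - c.mean()
    ss = float(cc @ cc)
    if ss == 0.0:
        return out
    # slope at each (sensor, sample): <cc, data> / <cc, cc>
    slopes = np.tensordot(cc, out.data, axes=(0, 0)) / ss
    out.data -= cc[:, None, None] * slopes[None, :, :]
    return out


def boxcar_smooth(arr: np.ndarray, size: int, axis: int = -1, edge: str = "truncate") -> np.ndarray:
    """Uniform (boxcar) moving average along ``axis``.

    ``edge='truncate'`` renormalises the kernel where it overhangs the array;
    ``edge='reflect'`` mirrors the data instead.
    """
    if size < 1:
        raise ValueError("kernel size must be >= 1")
    if size == 1:
        return arr.copy()
    if edge == "reflect":
        return uniform_filter1d(arr, size=size, axis=axis, mode="reflect")
    if edge != "truncate":
        raise ValueError(f"unknown edge rule {edge!r}")
    smoothed = uniform_filter1d(arr, size=size, axis=axis, mode="constant", cval=0.0)
    counts = uniform_filter1d(
        np.ones(arr.shape[axis]), size=size, mode="constant", cval=0.0
    )
    shape = [1] * arr.ndim
    shape[axis] = arr.shape[axis]
    return smoothed / counts.reshape(shape)


def smooth_epochs(rec: EpochedRecording, n_samples: int = 7, edge: str = "truncate") -> EpochedRecording:
    """Boxcar-smooth each trial/sensor time course over ``n_samples`` (7 = 28 ms at 250 Hz)."""
    out = rec.copy()
    out.data = boxcar_smooth(out.data, n_samples, axis=-1, edge=edge)
    return out
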