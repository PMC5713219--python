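"""Per-frame RMSD series, per-residue RMSF, and windowed mean ± SD statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Selection, Structure, Trajectory, kabsch_superpose

__all__ = ["SeriesStats", "rmsd_series", "rmsf", "window_stats", "mean_structure_coords"]


@dataclass(frozen=True)
class SeriesStats:
    """Mean and population standard deviation over a frame window."""

    mean: float
    sd: float
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation cannot be negative")
        if self.window[1] <= self.window[0]:
            raise ValueError("window must be nonempty")


def rmsd_series(
    traj: Trajectory,
    reference: Structure | np.ndarray,
    selection: Selection,
    superpose: bool = True,
) -> np.ndarray:
    """Cα (or any selection) RMSD of every frame against a reference.

    With ``superpose=True`` each frame is first least-squares fitted onto the
    reference selection; otherwise the deviation is taken in the shared frame
    of reference.
    """
    selection.validate(traj.topology)
    ref_coords = reference.coords if isinstance(reference, Structure) else np.asarray(reference)
    ref_sel = selection.apply(ref_coords)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mobile = selection.apply(traj.frames[f])
        if superpose:
            _, out[f] = kabsch_superpose(mobile, ref_sel)
        else:
            out[f] = np.sqrt(np.mean(np.sum((mobile - ref_sel) ** 2, axis=1)))
    return out


def mean_structure_coords(
    traj: Trajectory,
    selection: Selection,
    window: tuple[int, int] | None = None,
    superpose: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Window-mean selection coordinates and the frames fitted onto them.

    The mean is refined once: frames are fitted onto the plain average, the
    average is recomputed from the fitted frames, and the frames are fitted
    onto that refined mean.  Returns ``(mean_coords, fitted_frames)`` with
    ``fitted_frames`` of shape (W, N, 3).
    """
    start, end = window if window is not None else (0, traj.n_frames)
    if not (0 <= start < end <= traj.n_frames):
        raise ValueError(f"invalid window {window} for {traj.n_frames} frames")
    coords = selection.apply(traj.frames[start:end])
    if not superpose:
        return coords.mean(axis=0), coords

    mean = coords.mean(axis=0)
    for _ in range(2):  # initial fit + one refinement pass
        fitted = np.stack([kabsch_superpose(frame, mean)[0] for frame in coords])
        mean = fitted.mean(axis=0)
    return mean, fitted


def rmsf(
    traj: Trajectory,
    selection: Selection,
    window: tuple[int, int] | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the window mean.

    ``RMSF_i = sqrt(⟨‖r_i − ⟨r_i⟩‖²⟩)`` after superposing every frame onto
    the window-mean structure (one refinement pass).  Order-free: shuffling
    frames leaves the result unchanged.
    """
    selection.validate(traj.topology)
    mean, fitted = mean_structure_coords(traj, selection, window, superpose)
    dev = fitted - mean
    return np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))


def window_stats(series: np.ndarray, start: int, end: int) -> SeriesStats:
    """Arithmetic mean and population SD of ``series[start:end]``."""
    series = np.asarray(series, dtype=float)
    if not (0 <= start < end <= len(series)):
        raise ValueError(f"empty or invalid window [{start}, {end}) for length {len(series)}")
    chunk = series[start:end]
    return SeriesStats(mean=float(chunk.mean()), sd=float(chunk.std()), window=(start, end))
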