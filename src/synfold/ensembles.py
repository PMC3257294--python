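"""Ensemble observables: radius of gyration, RMSF, running averages."""

from __future__ import annotations

import warnings

import numpy as np

from .errors import ValidationError
from .structure import Structure, Trajectory, TrajectoryEnsemble
from .helix_geometry import superpose

#: approximate atomic masses for optional mass weighting
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974}


def radius_of_gyration(coords: np.ndarray, indices: np.ndarray | None = None,
                       masses: np.ndarray | None = None) -> float:
    """Root-mean-square distance of the selected atoms from their centroid.

    Unweighted by default; pass ``masses`` for mass weighting (differs
    from the unweighted value by under a percent for heavy-atom protein
    selections).
    """
    x = np.asarray(coords, dtype=float)
    if indices is not None:
        x = x[np.asarray(indices)]
    if x.shape[0] < 1:
        raise ValidationError("radius of gyration needs at least one atom")
    if masses is None:
        center = x.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((x - center) ** 2, axis=1))))
    w = np.asarray(masses, dtype=float)
    center = (w[:, None] * x).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((x - center) ** 2, axis=1)).sum()
                         / w.sum()))


def masses_for(structure: Structure, indices: np.ndarray) -> np.ndarray:
    return np.array([_MASSES.get(str(e).upper(), 12.011)
                     for e in structure.elements[indices]])


def rg_series(run: Trajectory, indices: np.ndarray) -> np.ndarray:
    """Per-frame radius of gyration over the selected atoms."""
    return np.array([radius_of_gyration(frame, indices)
                     for frame in run.coords])


def rmsf(frames: np.ndarray, selection: np.ndarray,
         reference: np.ndarray) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the ensemble mean.

    Every frame is first superposed on ``reference`` over the selected
    atoms, so rigid-body motion contributes nothing.
    """
    frames = np.asarray(frames, dtype=float)
    sel = np.asarray(selection)
    ref = np.asarray(reference, dtype=float)[sel]
    if frames.shape[0] < 2:
        warnings.warn("RMSF of a single frame is identically zero")
        return np.zeros(sel.size)
    fitted = np.empty((frames.shape[0], sel.size, 3))
    for f, frame in enumerate(frames):
        rot, t, _ = superpose(frame[sel], ref)
        fitted[f] = frame[sel] @ rot.T + t
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def ensemble_rmsf(ensemble: TrajectoryEnsemble, selection: np.ndarray,
                  reference: Structure) -> np.ndarray:
    frames = np.concatenate([run.coords for run in ensemble.runs])
    return rmsf(frames, selection, reference.coords)


def running_average(series: np.ndarray, window_ps: float,
                    dt: float) -> np.ndarray:
    """Centered moving mean over a window of ``window_ps`` picoseconds.

    At the edges the window is truncated to the available samples (no
    padding or reflection).
    """
    y = np.asarray(series, dtype=float)
    if window_ps < dt:
        raise ValidationError("running-average window must be >= dt")
    n = int(round(window_ps / dt))
    if n <= 1:
        return y.copy()
    left = (n - 1) // 2
    right = n // 2
    kernel = np.ones(n)
    # full[j] sums y over [j-n+1, j]; element i must cover [i-left, i+right],
    # hence j = i + right
    sums = np.convolve(y, kernel, mode="full")[right: right + y.size]
    counts = np.convolve(np.ones_like(y), kernel,
                         mode="full")[right: right + y.size]
    return sums / counts
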