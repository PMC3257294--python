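"""Umbrella-sampling bookkeeping and 1D WHAM.

Umbrella sampling biases a reaction coordinate x with harmonic
restraints ``w_i(x) = k/2 (x - x0_i)^2`` placed at staggered centers.
The weighted histogram analysis method (WHAM) recovers the unbiased
probability p(x) by self-consistent iteration of

    p_j   = sum_i n_ij / sum_i N_i exp[(f_i - w_i(x_j)) / kT]
    f_i   = -kT ln sum_j exp(-w_i(x_j)/kT) p_j

over bins j and windows i, where N_i is the sample count of window i
and f_i its free-energy constant.  The PMF is ``-kT ln p`` with the
minimum anchored at zero.  Convergence of a dataset is diagnosed by
solving WHAM separately on the first and second halves of every
window's samples and reporting the maximum PMF discrepancy.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ComputationError, ValidationError

#: Boltzmann constant in kcal/(mol K)
KB_KCAL = 0.0019872041
#: default simulation temperature (K)
DEFAULT_TEMPERATURE = 300.0
#: default bin width (A), small relative to the 0.5 A window spacing
DEFAULT_BIN_WIDTH = 0.1


@dataclasses.dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic restraint."""

    center: float  # A
    force_constant: float  # kcal/mol/A^2
    samples: np.ndarray  # A
    temperature: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant < 0:
            raise ValidationError("force constant must be >= 0")
        if self.samples.size < 1:
            raise ValidationError("window must contain at least one sample")

    def bias(self, x: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_constant * (x - self.center) ** 2


@dataclasses.dataclass
class PMF1D:
    bin_centers: np.ndarray  # A
    free_energy: np.ndarray  # kcal/mol, nan on empty bins, min = 0
    window_constants: np.ndarray  # f_i, kcal/mol
    n_iterations: int
    occupied: np.ndarray  # bool mask


def _check_overlap(windows: Sequence[UmbrellaWindow], edges: np.ndarray
                   ) -> None:
    ordered = sorted(windows, key=lambda w: w.center)
    for a, b in zip(ordered[:-1], ordered[1:]):
        ha = np.histogram(a.samples, bins=edges)[0] > 0
        hb = np.histogram(b.samples, bins=edges)[0] > 0
        if not np.any(ha & hb):
            raise ValidationError(
                f"umbrella windows at {a.center} and {b.center} A share no "
                "occupied bin; the histograms do not overlap")


def wham_solve(windows: Sequence[UmbrellaWindow],
               bin_width: float = DEFAULT_BIN_WIDTH,
               tolerance: float = 1e-7,
               max_iterations: int = 100000,
               edges: np.ndarray | None = None) -> PMF1D:
    """Self-consistent WHAM solution for 1D umbrella-sampled data.

    ``tolerance`` is the convergence threshold on the window constants
    f_i in kcal/mol.  ``edges`` overrides the automatic binning (used to
    put two datasets on a common grid).  Raises on non-overlapping
    windows and on non-convergence.
    """
    if not windows:
        raise ValidationError("need at least one umbrella window")
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise ValidationError("all windows must share one temperature")
    kt = KB_KCAL * windows[0].temperature
    if edges is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        edges = lo + np.arange(n_bins + 1) * bin_width
    else:
        edges = np.asarray(edges, dtype=float)
        n_bins = edges.size - 1
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(windows) > 1:
        _check_overlap(windows, edges)

    counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                       for w in windows]).astype(float)
    n_total = counts.sum(axis=0)  # per bin
    n_i = counts.sum(axis=1)  # per window
    bias = np.stack([w.bias(centers) for w in windows])  # (n_win, n_bins)
    boltz = np.exp(-bias / kt)

    f = np.zeros(len(windows))
    for iteration in range(1, max_iterations + 1):
        denom = (n_i[:, None] * np.exp(f[:, None] / kt) * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, n_total / denom, 0.0)
        z = (boltz * p[None, :]).sum(axis=1)
        f_new = -kt * np.log(z)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tolerance:
            break
    else:
        raise ComputationError(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(last max |delta f| = {delta:.3g} kcal/mol)")

    occupied = n_total > 0
    free = np.full(n_bins, np.nan)
    with np.errstate(divide="ignore"):
        free[occupied] = -kt * np.log(p[occupied])
    free[occupied] -= np.nanmin(free[occupied])
    return PMF1D(bin_centers=centers, free_energy=free, window_constants=f,
                 n_iterations=iteration, occupied=occupied)


def convergence_check(windows: Sequence[UmbrellaWindow],
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      tolerance: float = 1e-7,
                      min_count: int = 100) -> float:
    """Maximum PMF discrepancy (kcal/mol) between data halves.

    WHAM is solved separately on the first and second halves of every
    window's samples on a shared bin grid; after anchoring both minima
    at zero the maximum absolute free-energy difference over commonly
    sampled bins is returned.  Bins with fewer than ``min_count`` total
    counts in either half are excluded: their free energies are
    statistics-dominated and say nothing about convergence.  Values
    around 0.2 kcal/mol or below indicate adequately converged sampling.
    """
    for w in windows:
        if w.samples.size < 2:
            raise ValidationError("every window needs >= 2 samples for a "
                                  "half-half comparison")
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    halves = []
    counts = []
    for part in (0, 1):
        sub = [dataclasses.replace(
            w, samples=(w.samples[: w.samples.size // 2] if part == 0
                        else w.samples[w.samples.size // 2:]))
            for w in windows]
        halves.append(wham_solve(sub, bin_width=bin_width,
                                 tolerance=tolerance, edges=edges))
        counts.append(sum(np.histogram(w.samples, bins=edges)[0]
                          for w in sub))
    a, b = halves
    both = (np.isfinite(a.free_energy) & np.isfinite(b.free_energy)
            & (counts[0] >= min_count) & (counts[1] >= min_count))
    if not both.any():
        raise ComputationError("halves share no adequately sampled bins")
    fa = a.free_energy[both] - a.free_energy[both].min()
    fb = b.free_energy[both] - b.free_energy[both].min()
    return float(np.max(np.abs(fa - fb)))


# ---------------------------------------------------------------------------
# Window metadata / sample file I/O (plain text, one value per line)
# ---------------------------------------------------------------------------

def read_samples(path: str) -> np.ndarray:
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                vals.append(float(line))
    if not vals:
        raise ValidationError(f"no samples in {path}")
    return np.asarray(vals)


def write_samples(samples: np.ndarray, path: str) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(samples).ravel():
            fh.write(f"{v:.8f}\n")


def read_windows(metadata_path: str) -> list[UmbrellaWindow]:
    """Read windows from a tab-separated metadata file.

    Columns: center, force constant, temperature, sample-file path
    (relative paths resolve against the metadata file's directory).
    """
    import os
    base = os.path.dirname(os.path.abspath(metadata_path))
    windows = []
    with open(metadata_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            center, k, temp, sample_path = line.split("\t")
            if not os.path.isabs(sample_path):
                sample_path = os.path.join(base, sample_path)
            windows.append(UmbrellaWindow(
                center=float(center), force_constant=float(k),
                temperature=float(temp), samples=read_samples(sample_path)))
    if not windows:
        raise ValidationError(f"no windows described in {metadata_path}")
    return windows


def write_pmf1d(pmf: PMF1D, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("bin_center_angstrom\tfree_energy_kcal_mol\n")
        for c, g in zip(pmf.bin_centers, pmf.free_energy):
            fh.write(f"{c:.6f}\t{'nan' if not np.isfinite(g) else f'{g:.6f}'}\n")
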