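"""Helix axes, rigid superposition and inter-helix orientation surfaces.

The packing of helices in a molten-globule ensemble is described by
re-orienting every conformation onto a reference helix and recording the
polar direction of the other helices.  Concretely each frame is
superposed on the reference segment's backbone, the frame is rotated so
the reference helix axis lies along -z, and the fitted axis of each
target segment is reported as spherical angles (theta, phi) with theta
the inclination from +z (so a target parallel to the reference maps to
theta = pi) and phi the azimuth.

The orientation free-energy surface is the negative log of the binned
(theta, phi) probability in kT units after dividing each bin by
sin(theta); this removes the Jacobian entropy of the polar angle so an
isotropic axis distribution yields a flat surface.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import ComputationError, ValidationError
from .secondary import HelixSegment
from .structure import Selection, Structure, Trajectory

#: default analysis temperature (K) of the conformational ensembles
ANALYSIS_TEMPERATURE = 305.0

BACKBONE_NAMES = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# Helix axis fitting (bisector construction over C-alpha quadruplets)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HelixAxis:
    direction: np.ndarray  # unit vector, N -> C sign
    centroid: np.ndarray  # A
    label: str = ""


def fit_helix_axis(calpha_coords: np.ndarray, label: str = "") -> HelixAxis:
    """Fit a helix axis from ordered C-alpha positions.

    For every quadruplet of consecutive C-alphas the two inner bisector
    vectors point toward the local axis; their cross product gives a
    local axis direction.  Local directions are sign-fixed N -> C,
    averaged and normalized.
    """
    p = np.asarray(calpha_coords, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValidationError("calpha_coords must be (n, 3)")
    n = p.shape[0]
    if n < 4:
        raise ValidationError("helix axis fit needs at least 4 C-alpha atoms")
    nc = p[-1] - p[0]
    locals_ = []
    for i in range(n - 3):
        p1, p2, p3, p4 = p[i:i + 4]
        b2 = (p1 - p2) + (p3 - p2)
        b3 = (p2 - p3) + (p4 - p3)
        d = np.cross(b2, b3)
        norm = np.linalg.norm(d)
        if norm < 1e-10:
            continue
        d = d / norm
        if np.dot(d, nc) < 0:
            d = -d
        locals_.append(d)
    if not locals_:
        raise ComputationError("degenerate (collinear) C-alpha geometry; "
                               "no local axis could be constructed")
    mean = np.mean(locals_, axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-10:
        raise ComputationError("local axis directions cancel; geometry is "
                               "not helix-like")
    return HelixAxis(direction=mean / norm, centroid=p.mean(axis=0),
                     label=label)


# ---------------------------------------------------------------------------
# Rigid-body superposition (Kabsch, proper rotations only)
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``mobile @ R.T + t`` the superposed
    coordinates.  The rotation is constrained to be proper (det = +1):
    mirror images are never matched by a reflection.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValidationError("point sets must both be (n, 3) with equal n")
    if x.shape[0] < 3:
        raise ValidationError("superposition needs at least 3 points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = xc.T @ yc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = y.mean(axis=0) - rot @ x.mean(axis=0)
    moved = xc @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - yc) ** 2, axis=1))))
    return rot, t, rmsd


def rmsd_after_superposition(a: np.ndarray, b: np.ndarray) -> float:
    return superpose(a, b)[2]


# ---------------------------------------------------------------------------
# Orientation analysis
# ---------------------------------------------------------------------------

def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def _segment_indices(structure: Structure, segment: HelixSegment,
                     atom_names: Sequence[str]) -> np.ndarray:
    return Selection(chain=segment.chain,
                     res_range=(segment.start, segment.stop),
                     atom_names=atom_names).resolve(structure)


@dataclasses.dataclass
class OrientationSamples:
    """(theta, phi) orientation samples of one target segment."""

    theta: np.ndarray  # rad, in [0, pi]
    phi: np.ndarray  # rad, in [-pi, pi)
    label: str = ""
    n_skipped: int = 0


def orient_ensemble(run: Trajectory, structure: Structure,
                    reference: Structure | None = None,
                    reference_segment: HelixSegment | None = None,
                    target_segments: Sequence[HelixSegment] = (),
                    ) -> dict[str, OrientationSamples]:
    """Orientation angles of target helices relative to a reference helix.

    Every frame is superposed on the reference structure using the
    backbone atoms of ``reference_segment``, then rotated so the
    reference segment's fitted axis points along -z; each target
    segment's fitted axis is reported as (theta, phi).
    """
    if reference_segment is None or not target_segments:
        raise ValidationError("reference_segment and target_segments required")
    ref = reference if reference is not None else structure
    ref_bb = _segment_indices(ref, reference_segment, BACKBONE_NAMES)
    ref_ca = _segment_indices(ref, reference_segment, ("CA",))
    frame_bb = _segment_indices(structure, reference_segment, BACKBONE_NAMES)
    ref_axis = fit_helix_axis(ref.coords[ref_ca]).direction
    r0 = _rotation_between(ref_axis, np.array([0.0, 0.0, -1.0]))
    target_ca = {seg.label or f"{seg.chain}:{seg.start}-{seg.stop}":
                 _segment_indices(structure, seg, ("CA",))
                 for seg in target_segments}
    results: dict[str, tuple[list, list, int]] = {
        label: ([], [], 0) for label in target_ca}
    for frame in run.coords:
        rot, _, _ = superpose(frame[frame_bb], ref.coords[ref_bb])
        for label, ca_idx in target_ca.items():
            thetas, phis, skipped = results[label]
            try:
                axis = fit_helix_axis(frame[ca_idx]).direction
            except (ComputationError, ValidationError):
                results[label] = (thetas, phis, skipped + 1)
                continue
            d = r0 @ (rot @ axis)
            thetas.append(float(np.arccos(np.clip(d[2], -1.0, 1.0))))
            phis.append(float(np.arctan2(d[1], d[0])))
    return {label: OrientationSamples(theta=np.asarray(t), phi=np.asarray(p),
                                      label=label, n_skipped=skipped)
            for label, (t, p, skipped) in results.items()}


# ---------------------------------------------------------------------------
# Jacobian-corrected orientation free-energy surface
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PMF2D:
    """2D free-energy grid in kT; unoccupied bins are masked, not filled."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # kT, min over occupied bins anchored at 0
    mask: np.ndarray  # True where occupied
    temperature: float
    x_label: str = "phi"
    y_label: str = "theta"

    def contour_levels(self, spacing_kt: float = 1.0,
                       max_kt: float = 7.0) -> np.ndarray:
        return np.arange(0.0, max_kt + 0.5 * spacing_kt, spacing_kt)


def orientation_pmf(samples: OrientationSamples, bins: int = 18,
                    temperature: float = ANALYSIS_TEMPERATURE) -> PMF2D:
    """Orientation free energy over (phi, theta) with Jacobian correction.

    Bin probabilities are divided by sin(theta) at the bin center before
    Boltzmann inversion, removing the polar-angle entropy so that an
    isotropic axis distribution gives a flat surface.
    """
    if samples.theta.size < 1:
        raise ValidationError("need at least one orientation sample")
    phi_edges = np.linspace(-np.pi, np.pi, bins + 1)
    theta_edges = np.linspace(0.0, np.pi, bins + 1)
    counts, _, _ = np.histogram2d(samples.phi, samples.theta,
                                  bins=[phi_edges, theta_edges])
    theta_centers = 0.5 * (theta_edges[:-1] + theta_edges[1:])
    p = counts / counts.sum()
    corrected = p / np.sin(theta_centers)[None, :]
    mask = counts > 0
    values = np.full_like(corrected, np.nan)
    values[mask] = -np.log(corrected[mask])
    values[mask] -= np.nanmin(values[mask])
    return PMF2D(x_edges=phi_edges, y_edges=theta_edges, values=values,
                 mask=mask, temperature=temperature)


def write_pmf2d(pmf: PMF2D, path: str) -> None:
    """Tab-separated matrix with edge headers; masked bins written as nan."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K={pmf.temperature} "
                 f"x={pmf.x_label} y={pmf.y_label} units=kT\n")
        fh.write("# x_edges\t" + "\t".join(f"{e:.6f}" for e in pmf.x_edges)
                 + "\n")
        fh.write("# y_edges\t" + "\t".join(f"{e:.6f}" for e in pmf.y_edges)
                 + "\n")
        for row in pmf.values:
            fh.write("\t".join("nan" if not np.isfinite(v) else f"{v:.6f}"
                               for v in row) + "\n")
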