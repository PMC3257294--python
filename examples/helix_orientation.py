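"""Inter-helix orientation angles and the Jacobian-corrected surface.

Builds a two-helix system with the reference helix along -z and the
target helix at a programmed orientation, scrambles it by random rigid
motions, and recovers the (theta, phi) packing angles.  Then computes
an orientation free-energy surface from isotropic axes to show that the
sin(theta) Jacobian correction yields a flat landscape.
"""

import numpy as np

from synfold import (HelixBuildSpec, HelixSegment, Structure, Trajectory,
                     build_helix, orient_ensemble, orientation_pmf)
from synfold.helix_geometry import OrientationSamples

theta_true, phi_true = np.deg2rad(70.0), np.deg2rad(-120.0)

ref = build_helix(HelixBuildSpec(12, theta=np.pi), res_start=1)
tgt = build_helix(HelixBuildSpec(12, theta=theta_true, phi=phi_true),
                  res_start=21)
tgt = tgt.with_coords(tgt.coords + np.array([15.0, 0.0, 0.0]))
system = Structure(
    atom_names=np.concatenate([ref.atom_names, tgt.atom_names]),
    elements=np.concatenate([ref.elements, tgt.elements]),
    res_ids=np.concatenate([ref.res_ids, tgt.res_ids]),
    res_names=np.concatenate([ref.res_names, tgt.res_names]),
    chain_ids=np.concatenate([ref.chain_ids, tgt.chain_ids]),
    coords=np.vstack([ref.coords, tgt.coords]))

rng = np.random.default_rng(7)
frames = []
for _ in range(5):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, np.pi)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    frames.append(system.coords @ rot.T + rng.normal(0, 10, 3))
run = Trajectory(coords=np.stack(frames), dt=10.0)

out = orient_ensemble(
    run, system,
    reference_segment=HelixSegment("A", 1, 12, "reference"),
    target_segments=[HelixSegment("A", 21, 32, "target")])["target"]
print(f"programmed orientation: theta = {np.rad2deg(theta_true):.1f} deg, "
      f"phi = {np.rad2deg(phi_true):.1f} deg")
print(f"recovered over {out.theta.size} rigidly scrambled frames: "
      f"theta = {np.rad2deg(out.theta).mean():.1f} deg, "
      f"phi = {np.rad2deg(out.phi).mean():.1f} deg")

v = rng.normal(size=(100000, 3))
v /= np.linalg.norm(v, axis=1, keepdims=True)
pmf = orientation_pmf(OrientationSamples(
    theta=np.arccos(np.clip(v[:, 2], -1, 1)),
    phi=np.arctan2(v[:, 1], v[:, 0])), bins=18)
centers = 0.5 * (pmf.y_edges[:-1] + pmf.y_edges[1:])
interior = (centers > 0.3) & (centers < np.pi - 0.3)
vals = pmf.values[:, interior]
print(f"isotropic-axis surface: interior deviation from flat = "
      f"{np.nanmax(np.abs(vals - np.nanmean(vals))):.3f} kT")
print()
print("The re-orientation puts the reference helix along -z, so theta")
print("and phi describe helix packing independent of global motion; the")
print("sin(theta) division removes the polar-angle entropy, making an")
print("orientation-free ensemble flat (residual is shot noise).")
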