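import numpy as np
import pytest

from synfold import ComputationError, ValidationError, synthetic
from synfold.helix_geometry import (OrientationSamples, fit_helix_axis,
                                    orient_ensemble, orientation_pmf,
                                    superpose)
from synfold.secondary import HelixSegment
from synfold.structure import Structure, Trajectory
from synfold.synthetic import HelixBuildSpec

from conftest import random_rotation


def angle_deg(a, b):
    return np.rad2deg(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


def quaternion_superpose_rmsd(mobile, reference):
    """Independent oracle: Horn's quaternion method for optimal RMSD."""
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    sxx = x.T @ y
    k = np.empty((4, 4))
    k[0, 0] = sxx[0, 0] + sxx[1, 1] + sxx[2, 2]
    k[0, 1] = k[1, 0] = sxx[1, 2] - sxx[2, 1]
    k[0, 2] = k[2, 0] = sxx[2, 0] - sxx[0, 2]
    k[0, 3] = k[3, 0] = sxx[0, 1] - sxx[1, 0]
    k[1, 1] = sxx[0, 0] - sxx[1, 1] - sxx[2, 2]
    k[1, 2] = k[2, 1] = sxx[0, 1] + sxx[1, 0]
    k[1, 3] = k[3, 1] = sxx[0, 2] + sxx[2, 0]
    k[2, 2] = -sxx[0, 0] + sxx[1, 1] - sxx[2, 2]
    k[2, 3] = k[3, 2] = sxx[1, 2] + sxx[2, 1]
    k[3, 3] = -sxx[0, 0] - sxx[1, 1] + sxx[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    ssq = np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * lam
    return np.sqrt(max(ssq, 0.0) / x.shape[0])


class TestHelixAxis:
    def test_axis_of_helix_built_along_z(self, ideal_helix):
        ca = ideal_helix.coords[ideal_helix.atom_names == "CA"]
        axis = fit_helix_axis(ca)
        assert angle_deg(axis.direction, [0.0, 0.0, 1.0]) < 1.0

    def test_rotated_helix_gives_rotated_axis(self, ideal_helix, rng):
        ca = ideal_helix.coords[ideal_helix.atom_names == "CA"]
        rot = random_rotation(rng)
        rotated = fit_helix_axis(ca @ rot.T)
        assert angle_deg(rotated.direction, rot @ [0.0, 0.0, 1.0]) < 1.0

    def test_agrees_with_principal_axis_oracle(self):
        # the principal axis of a helix is only unbiased over whole
        # turns (~96.6 degrees/residue here): 20 residues comes closest,
        # keeping the oracle's own tilt well below the tolerance
        helix = synthetic.build_helix(HelixBuildSpec(n_residues=20))
        ca = helix.coords[helix.atom_names == "CA"]
        centered = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        pca = vt[0] if vt[0] @ (ca[-1] - ca[0]) > 0 else -vt[0]
        axis = fit_helix_axis(ca)
        assert angle_deg(axis.direction, pca) < 2.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_helix_axis(np.zeros((3, 3)))

    def test_collinear_points_rejected(self):
        pts = np.outer(np.arange(6), [1.0, 0.0, 0.0])
        with pytest.raises(ComputationError):
            fit_helix_axis(pts)


class TestSuperpose:
    def test_rigid_copy_recovered_exactly(self, rng):
        cloud = rng.normal(size=(10, 3))
        rot = random_rotation(rng)
        moved = cloud @ rot.T + np.array([4.0, 5.0, -6.0])
        r, t, rmsd = superpose(moved, cloud)
        assert rmsd < 1e-10
        np.testing.assert_allclose(moved @ r.T + t, cloud, atol=1e-9)

    def test_mirror_image_gets_proper_rotation(self, rng):
        cloud = rng.normal(size=(10, 3))
        mirrored = cloud * np.array([1.0, 1.0, -1.0])
        r, _, rmsd = superpose(mirrored, cloud)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            assert superpose(a, b)[2] == pytest.approx(
                quaternion_superpose_rmsd(a, b), abs=1e-6)

    def test_rmsd_is_symmetric_and_zero_iff_congruent(self, rng):
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        assert superpose(a, b)[2] == pytest.approx(superpose(b, a)[2],
                                                   abs=1e-9)
        assert superpose(a, a.copy())[2] < 1e-12

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValidationError):
            superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


def two_helix_structure(theta, phi):
    ref = synthetic.build_helix(HelixBuildSpec(12, theta=np.pi),
                                res_start=1)  # reference along -z
    tgt = synthetic.build_helix(HelixBuildSpec(12, theta=theta, phi=phi),
                                res_start=21)
    tgt = tgt.with_coords(tgt.coords + np.array([15.0, 0.0, 0.0]))
    return Structure(
        atom_names=np.concatenate([ref.atom_names, tgt.atom_names]),
        elements=np.concatenate([ref.elements, tgt.elements]),
        res_ids=np.concatenate([ref.res_ids, tgt.res_ids]),
        res_names=np.concatenate([ref.res_names, tgt.res_names]),
        chain_ids=np.concatenate([ref.chain_ids, tgt.chain_ids]),
        coords=np.vstack([ref.coords, tgt.coords]))


REF_SEG = HelixSegment("A", 1, 12, "ref")
TGT_SEG = HelixSegment("A", 21, 32, "tgt")


class TestOrientEnsemble:
    @pytest.mark.parametrize("theta_deg,phi_deg", [(70, -120), (30, 45),
                                                   (120, 160)])
    def test_recovers_programmed_angles_under_rigid_motion(
            self, theta_deg, phi_deg, rng):
        theta, phi = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
        s = two_helix_structure(theta, phi)
        frames = []
        for _ in range(3):
            rot = random_rotation(rng)
            frames.append(s.coords @ rot.T + rng.normal(0, 5, 3))
        run = Trajectory(coords=np.stack(frames), dt=10.0)
        out = orient_ensemble(run, s, reference_segment=REF_SEG,
                              target_segments=[TGT_SEG])["tgt"]
        assert np.all(np.rad2deg(np.abs(out.theta - theta)) < 2.0)
        phi_err = np.angle(np.exp(1j * (out.phi - phi)))
        assert np.all(np.rad2deg(np.abs(phi_err)) < 2.0)

    def test_target_parallel_to_reference_has_theta_pi(self):
        s = two_helix_structure(np.pi, 0.0)  # both along -z
        run = Trajectory(coords=s.coords[None], dt=10.0)
        out = orient_ensemble(run, s, reference_segment=REF_SEG,
                              target_segments=[TGT_SEG])["tgt"]
        assert out.theta[0] == pytest.approx(np.pi, abs=np.deg2rad(2))


class TestOrientationPMF:
    def test_single_point_mass_anchored_at_zero(self):
        samples = OrientationSamples(theta=np.full(100, 1.0),
                                     phi=np.full(100, 0.5))
        pmf = orientation_pmf(samples, bins=18)
        occupied = pmf.values[pmf.mask]
        assert occupied.size == 1
        assert occupied[0] == 0.0

    def test_duplicating_samples_leaves_pmf_unchanged(self, rng):
        v = rng.normal(size=(2000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        theta = np.arccos(np.clip(v[:, 2], -1, 1))
        phi = np.arctan2(v[:, 1], v[:, 0])
        once = orientation_pmf(OrientationSamples(theta=theta, phi=phi))
        twice = orientation_pmf(OrientationSamples(
            theta=np.tile(theta, 2), phi=np.tile(phi, 2)))
        np.testing.assert_allclose(once.values[once.mask],
                                   twice.values[twice.mask])

    def test_isotropic_axes_give_flat_interior(self, rng):
        v = rng.normal(size=(100000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        pmf = orientation_pmf(OrientationSamples(
            theta=np.arccos(np.clip(v[:, 2], -1, 1)),
            phi=np.arctan2(v[:, 1], v[:, 0])), bins=18)
        centers = 0.5 * (pmf.y_edges[:-1] + pmf.y_edges[1:])
        interior = (centers > 0.3) & (centers < np.pi - 0.3)
        vals = pmf.values[:, interior]
        deviation = vals - np.nanmean(vals)
        assert np.nanmax(np.abs(deviation)) < 0.2

    def test_gaussian_in_theta_matches_analytic_shape(self, rng):
        # density ~ sin(theta) exp(-(theta-pi/2)^2 / 2 sigma^2): after the
        # Jacobian correction the PMF is the quadratic itself
        sigma, n = 0.5, 200000
        theta = []
        while len(theta) < n:
            cand = rng.normal(np.pi / 2, sigma, 50000)
            cand = cand[(cand > 0) & (cand < np.pi)]
            keep = rng.random(cand.size) < np.sin(cand)
            theta.extend(cand[keep].tolist())
        theta = np.asarray(theta[:n])
        phi = rng.uniform(-np.pi, np.pi, n)
        pmf = orientation_pmf(OrientationSamples(theta=theta, phi=phi),
                              bins=18)
        centers = 0.5 * (pmf.y_edges[:-1] + pmf.y_edges[1:])
        analytic = np.broadcast_to((centers - np.pi / 2) ** 2
                                   / (2 * sigma ** 2), pmf.values.shape)
        counts, _, _ = np.histogram2d(phi, theta,
                                      bins=[pmf.x_edges, pmf.y_edges])
        well_sampled = counts >= 1000
        diff = pmf.values[well_sampled] - analytic[well_sampled]
        diff -= diff.mean()  # the PMF constant is arbitrary
        assert np.max(np.abs(diff)) < 0.15

    def test_contour_levels_every_kt_up_to_seven(self):
        samples = OrientationSamples(theta=np.full(10, 1.0),
                                     phi=np.full(10, 0.5))
        pmf = orientation_pmf(samples)
        np.testing.assert_allclose(pmf.contour_levels(), np.arange(8.0))
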