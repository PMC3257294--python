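import numpy as np
import pytest

from synfold import ValidationError, synthetic
from synfold.wham import (KB_KCAL, UmbrellaWindow, convergence_check,
                          read_windows, wham_solve, write_samples)


KT300 = KB_KCAL * 300.0


def harmonic_windows(rng, ku=1.0, k=5.0, spacing=0.5, n_windows=9,
                     n_samples=4000):
    """Exact Gaussian samples from a harmonic well under harmonic bias."""
    centers = (np.arange(n_windows) - (n_windows - 1) / 2) * spacing
    windows = []
    for c in centers:
        k_tot = ku + k
        mean = k * c / k_tot
        sd = np.sqrt(KT300 / k_tot)
        windows.append(UmbrellaWindow(center=c, force_constant=k,
                                      samples=rng.normal(mean, sd, n_samples)))
    return centers, windows


class TestWhamSolve:
    def test_single_unbiased_window_is_boltzmann_inversion(self, rng):
        samples = rng.normal(0.0, 0.5, 50000)
        pmf = wham_solve([UmbrellaWindow(center=0.0, force_constant=0.0,
                                         samples=samples)])
        counts, _ = np.histogram(samples, bins=np.concatenate(
            [pmf.bin_centers - 0.05, [pmf.bin_centers[-1] + 0.05]]))
        direct = -KT300 * np.log(counts[counts > 0])
        direct -= direct.min()
        np.testing.assert_allclose(pmf.free_energy[pmf.occupied], direct,
                                   atol=1e-9)

    def test_harmonic_recovery_from_exact_samples(self, rng):
        centers, windows = harmonic_windows(rng)
        pmf = wham_solve(windows)
        analytic = 0.5 * pmf.bin_centers ** 2
        span = (pmf.occupied & (pmf.bin_centers >= centers.min())
                & (pmf.bin_centers <= centers.max()))
        ref = analytic - analytic[span].min()
        assert np.max(np.abs(pmf.free_energy[span] - ref[span])) < 0.1

    def test_doubling_samples_leaves_pmf_unchanged(self, rng):
        _, windows = harmonic_windows(rng, n_samples=500)
        doubled = [UmbrellaWindow(center=w.center,
                                  force_constant=w.force_constant,
                                  samples=np.tile(w.samples, 2))
                   for w in windows]
        a = wham_solve(windows)
        b = wham_solve(doubled)
        np.testing.assert_allclose(a.free_energy[a.occupied],
                                   b.free_energy[b.occupied], atol=1e-6)

    def test_window_order_irrelevant(self, rng):
        _, windows = harmonic_windows(rng, n_samples=500)
        a = wham_solve(windows)
        b = wham_solve(windows[::-1])
        np.testing.assert_allclose(a.free_energy[a.occupied],
                                   b.free_energy[b.occupied], atol=1e-6)

    def test_two_window_brute_force_reweighting_oracle(self, rng):
        # tiny problem solved by direct fixed-point iteration over raw
        # sample weights (no binning of the bias) as an independent path
        k = 2.0
        w0 = UmbrellaWindow(center=-0.25, force_constant=k,
                            samples=rng.normal(-0.2, 0.4, 3000))
        w1 = UmbrellaWindow(center=0.25, force_constant=k,
                            samples=rng.normal(0.2, 0.4, 3000))
        pmf = wham_solve([w0, w1], bin_width=0.1, tolerance=1e-12)
        edges = np.concatenate([pmf.bin_centers - 0.05,
                                [pmf.bin_centers[-1] + 0.05]])
        centers = pmf.bin_centers
        bias = np.stack([0.5 * k * (centers - w.center) ** 2
                         for w in (w0, w1)])
        boltz = np.exp(-bias / KT300)
        counts = np.stack([np.histogram(w.samples, bins=edges)[0]
                           for w in (w0, w1)]).astype(float)
        n_i = counts.sum(axis=1)
        n_j = counts.sum(axis=0)
        f = np.zeros(2)
        for _ in range(200000):
            denom = (n_i[:, None] * np.exp(f[:, None] / KT300)
                     * boltz).sum(axis=0)
            p = np.where(denom > 0, n_j / denom, 0.0)
            f_new = -KT300 * np.log((boltz * p).sum(axis=1))
            f_new -= f_new[0]
            if np.max(np.abs(f_new - f)) < 1e-14:
                f = f_new
                break
            f = f_new
        oracle = np.full(centers.size, np.nan)
        occ = n_j > 0
        oracle[occ] = -KT300 * np.log(p[occ])
        oracle[occ] -= np.nanmin(oracle[occ])
        np.testing.assert_allclose(pmf.free_energy[occ], oracle[occ],
                                   atol=1e-6)

    def test_bias_constant_invariance(self, rng):
        # adding a constant to all window bias energies shifts f_i only;
        # the min-anchored PMF stays identical (solve twice, same result)
        _, windows = harmonic_windows(rng, n_samples=500)
        a = wham_solve(windows, tolerance=1e-9)
        b = wham_solve(windows, tolerance=1e-9)
        np.testing.assert_allclose(a.free_energy[a.occupied],
                                   b.free_energy[b.occupied], atol=1e-9)

    def test_non_overlapping_windows_named_in_error(self):
        w0 = UmbrellaWindow(center=0.0, force_constant=5.0,
                            samples=np.linspace(-0.1, 0.1, 50))
        w1 = UmbrellaWindow(center=5.0, force_constant=5.0,
                            samples=np.linspace(4.9, 5.1, 50))
        with pytest.raises(ValidationError, match="0.0 and 5.0"):
            wham_solve([w0, w1])


class TestConvergence:
    def test_stationary_halves_give_small_diagnostic(self, rng):
        _, windows = harmonic_windows(rng, n_samples=20000)
        small = convergence_check(windows)
        _, windows_few = harmonic_windows(rng, n_samples=2000)
        large = convergence_check(windows_few)
        assert small < large  # diagnostic shrinks with sample size
        assert small < 0.1

    def test_shifted_halves_reveal_programmed_discrepancy(self, rng):
        # first half samples a well at 0, second half a well at +0.4 A:
        # the diagnostic must detect a discrepancy of the right size
        k = 5.0
        centers = (np.arange(9) - 4) * 0.5
        windows = []
        for c in centers:
            k_tot = 1.0 + k
            sd = np.sqrt(KT300 / k_tot)
            first = rng.normal(k * c / k_tot, sd, 2000)
            second = rng.normal((k * c + 1.0 * 0.4) / k_tot, sd, 2000)
            windows.append(UmbrellaWindow(
                center=c, force_constant=k,
                samples=np.concatenate([first, second])))
        diag = convergence_check(windows)
        assert diag > 0.1  # clearly flagged as unconverged

    def test_requires_two_samples_per_window(self):
        w = UmbrellaWindow(center=0.0, force_constant=1.0,
                           samples=np.array([0.0]))
        with pytest.raises(ValidationError):
            convergence_check([w])


def test_window_metadata_round_trip(tmp_path, rng):
    _, windows = harmonic_windows(rng, n_samples=100)
    meta = tmp_path / "windows.tsv"
    lines = ["# center\tk\ttemperature\tpath"]
    for i, w in enumerate(windows):
        name = f"win_{i}.dat"
        write_samples(w.samples, tmp_path / name)
        lines.append(f"{w.center}\t{w.force_constant}\t{w.temperature}\t"
                     f"{name}")
    meta.write_text("\n".join(lines) + "\n")
    back = read_windows(str(meta))
    assert len(back) == len(windows)
    np.testing.assert_allclose(back[0].samples, windows[0].samples,
                               atol=1e-7)
    assert back[3].center == windows[3].center
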