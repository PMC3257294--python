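"""Exponential kinetics of ensemble-averaged traces and pseudo free-energy
surfaces.

Ensemble-averaged native-contact fractions and helicities from a set of
independent high-temperature unfolding runs relax, on the baseline
level, as single exponentials ``A exp(-t/tau) + B``.  The fit excludes
an initial burn phase (the ultrafast sub-20-ps decay of tightly packed
contacts), reports the relaxation time tau (ns), amplitude A, plateau B,
and the Pearson correlation coefficient R between fitted and observed
values as the fit-quality measure.

A pseudo free-energy surface bins pooled (Q_inter, Q_NCBD) samples from
an early time window and Boltzmann-inverts the histogram.  Because the
runs are not equilibrated, the surface is qualitative: it reveals
intermediate-state basins but its depths depend on initial conditions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

from .errors import ComputationError, ValidationError

#: default start of the fit window (ns): skips the ultrafast initial decay
DEFAULT_FIT_START = 0.02
#: multi-start initial relaxation times (ns)
TAU_STARTS = (0.1, 1.0, 5.0)


@dataclasses.dataclass
class KineticFit:
    """Parameters of ``A exp(-t/tau) + B`` plus fit quality."""

    tau: float  # ns
    amplitude: float  # A
    offset: float  # B
    correlation: float  # Pearson R between fitted and observed values
    model: str = "single"
    fit_start: float = DEFAULT_FIT_START  # ns
    identifiable: bool = True
    # second component, populated only for the double-exponential model
    tau2: float | None = None
    amplitude2: float | None = None


def _single(t, a, tau, b):
    return a * np.exp(-t / tau) + b


def fit_exponential(time_ns: np.ndarray, y: np.ndarray,
                    model: str = "single",
                    fit_start: float = DEFAULT_FIT_START,
                    noise_model: str = "ar1") -> KineticFit:
    """Nonlinear least-squares exponential fit of an averaged trace.

    ``time_ns`` is the time grid in ns and ``y`` the averaged observable
    bounded in [0, 1].  Fitting starts at ``fit_start`` ns.

    Ensemble means of relaxing two-state observables carry noise that is
    serially correlated on the relaxation timescale itself, so the
    default ``noise_model="ar1"`` minimizes AR(1)-whitened residuals
    (iterating the whitening constant with the current tau estimate),
    which is the efficient least-squares estimator for such traces;
    ``noise_model="iid"`` gives the plain unweighted fit.  Both fit the
    same model ``A exp(-t/tau) + B``.

    A constant trace has no identifiable relaxation time and is returned
    flagged with ``identifiable=False`` (tau = nan, A = 0, B = mean).
    """
    t = np.asarray(time_ns, dtype=float)
    yy = np.asarray(y, dtype=float)
    if t.shape != yy.shape:
        raise ValidationError("time and trace must have equal length")
    mask = t >= fit_start
    if mask.sum() < 10:
        raise ValidationError("need at least 10 points after fit_start")
    t, yy = t[mask], yy[mask]
    if np.min(yy) < -1e-9 or np.max(yy) > 1 + 1e-9:
        raise ValidationError("trace must be bounded in [0, 1]")
    if np.std(yy) < 1e-12:
        return KineticFit(tau=float("nan"), amplitude=0.0,
                          offset=float(np.mean(yy)), correlation=float("nan"),
                          model=model, fit_start=fit_start,
                          identifiable=False)
    if noise_model not in ("ar1", "iid"):
        raise ValidationError(f"unknown noise model {noise_model!r}")
    if model == "single":
        return _fit_single(t, yy, fit_start, noise_model)
    if model == "double":
        return _fit_double(t, yy, fit_start)
    raise ValidationError(f"unknown model {model!r}")


def _whitened_residuals(t: np.ndarray, yy: np.ndarray, params: np.ndarray,
                        rho: float) -> np.ndarray:
    r = yy - _single(t, *params)
    if rho == 0.0:
        return r
    return np.concatenate([[r[0] * np.sqrt(1.0 - rho ** 2)],
                           r[1:] - rho * r[:-1]])


def _fit_single(t: np.ndarray, yy: np.ndarray, fit_start: float,
                noise_model: str) -> KineticFit:
    a0 = float(np.clip(yy[0] - yy[-1], 1e-3, 1.0))
    b0 = float(np.clip(yy[-1], 0.0, 1.0))
    dt = float(np.median(np.diff(t)))
    lower = np.array([0.0, 1e-6, 0.0])
    upper = np.array([1.0, np.inf, 1.0])
    best = None
    best_res = np.inf
    for tau0 in TAU_STARTS:
        x = np.clip([a0, tau0, b0], lower, None)
        tau_c = tau0
        try:
            # for AR(1) noise, iterate the whitening constant to
            # self-consistency with the current tau estimate
            n_rounds = 6 if noise_model == "ar1" else 1
            for _ in range(n_rounds):
                rho = (np.exp(-dt / tau_c) if noise_model == "ar1" else 0.0)
                sol = optimize.least_squares(
                    lambda p: _whitened_residuals(t, yy, p, rho),
                    x0=x, bounds=(lower, upper), max_nfev=20000)
                x = sol.x
                if abs(x[1] - tau_c) < 1e-10:
                    tau_c = x[1]
                    break
                tau_c = x[1]
        except (RuntimeError, ValueError):
            continue
        if noise_model == "ar1":
            # AR(1) profile criterion: residual term plus the whitening
            # Jacobian, so candidates with different rho are comparable
            rho = np.exp(-dt / x[1])
            ssq_w = float(np.sum(_whitened_residuals(t, yy, x, rho) ** 2))
            res = 0.5 * t.size * np.log(ssq_w) - 0.5 * np.log(1 - rho ** 2)
        else:
            res = float(np.sum((_single(t, *x) - yy) ** 2))
        if res < best_res:
            best_res, best = res, x
    if best is None:
        raise ComputationError("exponential fit failed to converge from all "
                               "starting points")
    a, tau, b = best
    fitted = _single(t, a, tau, b)
    if np.std(fitted) < 1e-12:
        r = float("nan")
    else:
        r = float(stats.pearsonr(fitted, yy)[0])
    return KineticFit(tau=float(tau), amplitude=float(a), offset=float(b),
                      correlation=r, model="single", fit_start=fit_start)


def _double(t, a1, tau1, a2, tau2, b):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + b


def _fit_double(t: np.ndarray, yy: np.ndarray, fit_start: float) -> KineticFit:
    """Double-exponential fit; noisy averaged traces rarely constrain it."""
    a0 = float(np.clip(yy[0] - yy[-1], 1e-3, 1.0)) / 2
    b0 = float(np.clip(yy[-1], 0.0, 1.0))
    best, best_res = None, np.inf
    for tau_fast in (0.05, 0.2):
        for tau_slow in (1.0, 5.0):
            try:
                popt, _ = optimize.curve_fit(
                    _double, t, yy, p0=[a0, tau_fast, a0, tau_slow, b0],
                    bounds=([0, 1e-6, 0, 1e-6, 0],
                            [1, np.inf, 1, np.inf, 1]), maxfev=40000)
            except (RuntimeError, ValueError):
                continue
            res = float(np.sum((_double(t, *popt) - yy) ** 2))
            if res < best_res:
                best_res, best = res, popt
    if best is None:
        raise ComputationError("double-exponential fit failed to converge")
    a1, tau1, a2, tau2, b = best
    if tau1 > tau2:  # report the slower component first
        a1, tau1, a2, tau2 = a2, tau2, a1, tau1
    fitted = _double(t, *best)
    r = float(stats.pearsonr(fitted, yy)[0])
    return KineticFit(tau=float(tau2), amplitude=float(a2), offset=float(b),
                      correlation=r, model="double", fit_start=fit_start,
                      tau2=float(tau1), amplitude2=float(a1))


# ---------------------------------------------------------------------------
# Pseudo free-energy surfaces over contact-fraction coordinates
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FreeEnergySurface2D:
    """Boltzmann-inverted histogram over two bounded order parameters.

    Built from non-equilibrium unfolding statistics: the surface is a
    qualitative map of basins, not an equilibrium free energy.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    values: np.ndarray  # kT, min anchored at 0
    mask: np.ndarray
    temperature: float
    equilibrium: bool = False


def pseudo_fes(x: np.ndarray, y: np.ndarray, bins: int = 25,
               temperature: float = 475.0,
               limits: tuple[float, float] = (0.0, 1.0)
               ) -> FreeEnergySurface2D:
    """Pseudo free-energy surface ``F = -ln p`` in kT from pooled samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or x.shape != y.shape:
        raise ValidationError("need equal-length, non-empty sample vectors")
    edges = np.linspace(limits[0], limits[1], bins + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[edges, edges])
    p = counts / counts.sum()
    mask = counts > 0
    values = np.full_like(p, np.nan)
    values[mask] = -np.log(p[mask])
    values[mask] -= np.nanmin(values[mask])
    return FreeEnergySurface2D(x_edges=edges, y_edges=edges, values=values,
                               mask=mask, temperature=temperature)


def write_fit_table(fits: dict[str, KineticFit], path: str) -> None:
    """Tab-separated fit table: observable, tau (ns), A, B, correlation R."""
    with open(path, "w") as fh:
        fh.write("observable\ttau_ns\tA\tB\tR\n")
        for name, fit in fits.items():
            fh.write(f"{name}\t{fit.tau:.6g}\t{fit.amplitude:.6g}\t"
                     f"{fit.offset:.6g}\t{fit.correlation:.6g}\n")
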