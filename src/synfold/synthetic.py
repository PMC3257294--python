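"""Synthetic inputs with known ground truth for every analysis stage.

Everything downstream of molecular dynamics can be exercised without MD:

* **Contact-trace ensembles** — every native contact in every run is an
  independent two-state Markov chain whose ensemble-mean formed fraction
  is exactly ``B + A exp(-t/tau)`` with ``A = p0 - p_inf`` and
  ``B = p_inf``, so fitted kinetic constants can be checked against the
  generator's parameters.  Rates are ``k_on = p_inf / tau`` and
  ``k_off = (1 - p_inf) / tau``.
* **Helical geometries** — ideal poly-alanine backbones (N, CA, C, O)
  built from dihedral angles, oriented along a requested axis, with
  optional coordinate jitter.
* **Umbrella samples** — Metropolis chains on an analytic 1D potential
  plus harmonic window restraints.
* **Toy two-chain complexes** — residue pairs placed at scripted
  distances, with trajectories that form and break planned contacts and
  salt bridges frame by frame.

All randomness flows through an explicitly passed seeded generator; a
fixed seed reproduces outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .helix_geometry import _rotation_between, fit_helix_axis
from .structure import Structure, Trajectory, TrajectoryEnsemble
from .wham import KB_KCAL, UmbrellaWindow


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Two-state Markov contact-trace ensembles
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SyntheticKineticsSpec:
    """Parameters of a two-state Markov contact ensemble.

    ``p0`` is the initial formed probability and ``p_inf`` the
    stationary one; the ensemble mean relaxes as
    ``p_inf + (p0 - p_inf) exp(-t/tau)``.
    """

    tau_ns: float
    p0: float
    p_inf: float
    n_runs: int = 50
    n_contacts: int = 62
    dt_ps: float = 10.0
    t_total_ns: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_ns <= 0:
            raise ValidationError("tau must be positive")
        for name in ("p0", "p_inf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.dt_ps >= self.tau_ns * 1e3:
            warnings.warn("frame interval is not smaller than the relaxation "
                          "time; the decay is undersampled")

    @classmethod
    def from_fit_params(cls, tau_ns: float, amplitude: float, offset: float,
                        **kwargs) -> "SyntheticKineticsSpec":
        """Parameterize from exponential-fit constants (A, B)."""
        return cls(tau_ns=tau_ns, p0=amplitude + offset, p_inf=offset,
                   **kwargs)

    @property
    def amplitude(self) -> float:
        return self.p0 - self.p_inf

    @property
    def offset(self) -> float:
        return self.p_inf


@dataclasses.dataclass
class ContactTraceEnsemble:
    """Per-run formed-fraction traces plus the generating ground truth."""

    times_ps: np.ndarray
    fractions: np.ndarray  # (n_runs, n_frames)
    spec: SyntheticKineticsSpec

    @property
    def times_ns(self) -> np.ndarray:
        return self.times_ps / 1000.0

    def mean(self) -> np.ndarray:
        return self.fractions.mean(axis=0)

    def expectation(self, t_ns: np.ndarray | None = None) -> np.ndarray:
        """Analytic ensemble mean ``p_inf + (p0 - p_inf) exp(-t/tau)``."""
        t = self.times_ns if t_ns is None else np.asarray(t_ns)
        s = self.spec
        return s.p_inf + (s.p0 - s.p_inf) * np.exp(-t / s.tau_ns)


def gen_contact_traces(spec: SyntheticKineticsSpec,
                       rng: np.random.Generator | None = None
                       ) -> ContactTraceEnsemble:
    """Simulate independent two-state contacts and return Q(t) per run.

    The per-step transition probabilities are the exact two-state
    propagator over one frame interval, so the ensemble mean matches the
    analytic exponential at every frame, not only in the small-step
    limit.
    """
    gen = _rng(spec.seed if rng is None else rng)
    n_frames = int(round(spec.t_total_ns * 1000.0 / spec.dt_ps)) + 1
    decay = np.exp(-spec.dt_ps / (spec.tau_ns * 1000.0))
    p_stay_formed = spec.p_inf + (1.0 - spec.p_inf) * decay
    p_become_formed = spec.p_inf * (1.0 - decay)
    state = gen.random((spec.n_runs, spec.n_contacts)) < spec.p0
    q = np.empty((spec.n_runs, n_frames))
    q[:, 0] = state.mean(axis=1)
    for f in range(1, n_frames):
        u = gen.random(state.shape)
        state = np.where(state, u < p_stay_formed, u < p_become_formed)
        q[:, f] = state.mean(axis=1)
    times = np.arange(n_frames) * spec.dt_ps
    return ContactTraceEnsemble(times_ps=times, fractions=q, spec=spec)


# ---------------------------------------------------------------------------
# Ideal peptide backbones from dihedral angles
# ---------------------------------------------------------------------------

# standard backbone geometry (lengths in A, angles in degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.7,
          "CA-C-O": 120.5}

#: ideal alpha-helix backbone dihedrals (degrees)
ALPHA_PHI, ALPHA_PSI = -57.0, -47.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
           angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(phi_psi: Sequence[tuple[float, float]],
                   chain: str = "A", res_start: int = 1,
                   res_name: str = "ALA") -> Structure:
    """Build an N, CA, C, O backbone from per-residue (phi, psi) degrees.

    omega is fixed at 180 degrees (trans peptide bonds).
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValidationError("need at least one residue")
    coords: list[np.ndarray] = []
    ang = np.deg2rad(180.0 - _ANGLE["N-CA-C"])
    n0 = np.zeros(3)
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    c0 = ca0 + _BOND["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    n_atoms, ca_atoms, c_atoms = [n0], [ca0], [c0]
    for i in range(1, n_res):
        psi_prev = phi_psi[i - 1][1]
        ni = _place(n_atoms[-1], ca_atoms[-1], c_atoms[-1],
                    _BOND["C-N"], _ANGLE["CA-C-N"], psi_prev)
        cai = _place(ca_atoms[-1], c_atoms[-1], ni,
                     _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        ci = _place(c_atoms[-1], ni, cai,
                    _BOND["CA-C"], _ANGLE["N-CA-C"], phi_psi[i][0])
        n_atoms.append(ni)
        ca_atoms.append(cai)
        c_atoms.append(ci)
    names, elements, res_ids = [], [], []
    for i in range(n_res):
        oi = _place(n_atoms[i], ca_atoms[i], c_atoms[i],
                    _BOND["C-O"], _ANGLE["CA-C-O"], phi_psi[i][1] + 180.0)
        coords.extend([n_atoms[i], ca_atoms[i], c_atoms[i], oi])
        names.extend(["N", "CA", "C", "O"])
        elements.extend(["N", "C", "C", "O"])
        res_ids.extend([res_start + i] * 4)
    n_total = 4 * n_res
    return Structure(
        atom_names=np.array(names, dtype="U5"),
        elements=np.array(elements, dtype="U2"),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.full(n_total, res_name, dtype="U4"),
        chain_ids=np.full(n_total, chain, dtype="U4"),
        coords=np.array(coords))


@dataclasses.dataclass
class HelixBuildSpec:
    """An ideal alpha-helix at a prescribed axis orientation."""

    n_residues: int
    theta: float = 0.0  # rad, polar angle of the axis (from +z)
    phi: float = 0.0  # rad, azimuth
    noise_sigma: float = 0.0  # A, isotropic Gaussian coordinate jitter
    seed: int = 0

    def axis(self) -> np.ndarray:
        return np.array([np.sin(self.theta) * np.cos(self.phi),
                         np.sin(self.theta) * np.sin(self.phi),
                         np.cos(self.theta)])


def build_helix(spec: HelixBuildSpec,
                rng: np.random.Generator | None = None,
                chain: str = "A", res_start: int = 1) -> Structure:
    """Ideal alpha-helix backbone oriented along the requested axis.

    The noiseless build has exact screw symmetry: all CA-CA(i, i+1)
    distances are identical (rise ~1.5 A, ~100 degrees twist per
    residue).
    """
    if spec.n_residues < 4:
        raise ValidationError("helix needs at least 4 residues")
    s = build_backbone([(ALPHA_PHI, ALPHA_PSI)] * spec.n_residues,
                       chain=chain, res_start=res_start)
    ca = s.coords[s.atom_names == "CA"]
    axis = fit_helix_axis(ca)
    rot = _rotation_between(axis.direction, spec.axis())
    coords = (s.coords - s.coords.mean(axis=0)) @ rot.T
    if spec.noise_sigma > 0:
        gen = _rng(spec.seed if rng is None else rng)
        coords = coords + gen.normal(0.0, spec.noise_sigma, coords.shape)
    return s.with_coords(coords)


def helix_coil_chain(helical: Sequence[bool], chain: str = "A",
                     res_start: int = 1) -> Structure:
    """A chain whose residues are helical or extended per the given flags."""
    pairs = [(ALPHA_PHI, ALPHA_PSI) if h else (180.0, 180.0)
             for h in helical]
    return build_backbone(pairs, chain=chain, res_start=res_start)


# ---------------------------------------------------------------------------
# Umbrella sampling of an analytic potential (Metropolis)
# ---------------------------------------------------------------------------

def sample_umbrella(potential: Callable[[float], float],
                    centers: Sequence[float], force_constant: float,
                    n_samples: int, temperature: float = 300.0,
                    rng: np.random.Generator | int | None = 0,
                    burn_in: int = 1000, step: float | None = None,
                    thin: int = 10) -> list[UmbrellaWindow]:
    """Metropolis samples of ``U(x) + k/2 (x - x0)^2`` per window.

    The default proposal width is about 2.4 standard deviations of the
    restraint alone, which keeps acceptance near 50% and decorrelates
    quickly together with the default thinning.
    """
    gen = _rng(rng)
    kt = KB_KCAL * temperature
    if step is None:
        step = 2.4 * np.sqrt(kt / max(force_constant, 0.25))
    windows = []
    for center in centers:
        def energy(x: float) -> float:
            return potential(x) + 0.5 * force_constant * (x - center) ** 2
        x = float(center)
        e = energy(x)
        samples = np.empty(n_samples)
        accepted = 0
        total = burn_in + n_samples * thin
        for i in range(total):
            xp = x + gen.normal(0.0, step)
            ep = energy(xp)
            if ep <= e or gen.random() < np.exp(-(ep - e) / kt):
                x, e = xp, ep
                accepted += 1
            if i >= burn_in and (i - burn_in) % thin == 0:
                samples[(i - burn_in) // thin] = x
        if accepted / total < 0.05:
            warnings.warn(f"window at {center}: Metropolis acceptance below "
                          "5%; samples may be poorly decorrelated")
        windows.append(UmbrellaWindow(center=center,
                                      force_constant=force_constant,
                                      samples=samples,
                                      temperature=temperature))
    return windows


# ---------------------------------------------------------------------------
# Toy two-chain complexes with scripted contacts and salt bridges
# ---------------------------------------------------------------------------

#: criterion atoms used when building salt-bridge residues
_SIDE_ATOM = {"ARG": "CZ", "LYS": "NZ", "ASP": "CG", "GLU": "CD", "ALA": "CB"}

_SPACING = 30.0  # A between residue sites along a chain
_FAR = 100.0  # A offset of the unformed chain-B position


@dataclasses.dataclass(frozen=True)
class PlannedPair:
    """One scripted inter-chain pair at a prescribed distance."""

    res_a: int  # chain A residue number
    res_b: int  # chain B residue number
    distance: float  # A between the pair's reference atoms
    res_name_a: str = "ALA"
    res_name_b: str = "ALA"


@dataclasses.dataclass
class ToyComplex:
    structure: Structure  # all planned pairs formed
    plan: list[PlannedPair]
    trajectory: Trajectory | None = None
    formed_per_frame: list[set[int]] | None = None  # plan indices


def build_toy_complex(n_res_a: int, n_res_b: int,
                      plan: Sequence[PlannedPair],
                      frame_plan: Sequence[set[int]] | None = None,
                      dt_ps: float = 10.0) -> ToyComplex:
    """Two chains with residue pairs placed at scripted distances.

    Chain A residues sit on a line; each planned chain-B residue is
    placed so that the minimal heavy-atom distance (and the salt-bridge
    criterion-atom distance, when the residue types are charged) to its
    chain-A partner equals exactly the planned distance.  Unplanned
    chain-B residues sit far away.  ``frame_plan`` scripts, per frame,
    which plan entries are formed; unformed entries are displaced to the
    far position.
    """
    plan = list(plan)
    used_b: set[int] = set()
    for p in plan:
        if not (1 <= p.res_a <= n_res_a and 1 <= p.res_b <= n_res_b):
            raise ValidationError(f"plan references missing residue: {p}")
        if p.res_b in used_b:
            raise ValidationError(
                f"chain-B residue {p.res_b} appears in two plan entries; "
                "each residue can realize only one scripted distance")
        used_b.add(p.res_b)

    res_names_a = {p.res_a: p.res_name_a for p in plan}
    res_names_b = {p.res_b: p.res_name_b for p in plan}

    def base_a(i: int) -> np.ndarray:
        return np.array([_SPACING * i, 0.0, 0.0])

    def base_b_far(j: int) -> np.ndarray:
        return np.array([_SPACING * j, _FAR, 0.0])

    formed_pos = {p.res_b: base_a(p.res_a) + np.array([p.distance, 0.0, 0.0])
                  for p in plan}

    names, elements, res_ids, res_names, chain_ids = [], [], [], [], []
    slots: list[tuple[str, int]] = []  # (chain, res) per atom

    def add_residue(chain: str, rid: int, rname: str) -> None:
        side = _SIDE_ATOM.get(rname, "CB")
        for atom in ("CA", side):
            names.append(atom)
            elements.append("N" if atom == "NZ" else "C")
            res_ids.append(rid)
            res_names.append(rname)
            chain_ids.append(chain)
            slots.append((chain, rid))

    for i in range(1, n_res_a + 1):
        add_residue("A", i, res_names_a.get(i, "ALA"))
    for j in range(1, n_res_b + 1):
        add_residue("B", j, res_names_b.get(j, "ALA"))

    def frame_coords(formed: set[int]) -> np.ndarray:
        pos_b = {}
        for idx, p in enumerate(plan):
            pos_b[p.res_b] = (formed_pos[p.res_b] if idx in formed
                              else base_b_far(p.res_b))
        out = np.empty((len(slots), 3))
        offset = np.array([0.0, 0.0, 1.5])  # side atom sits above CA
        for a, (chain, rid) in enumerate(slots):
            base = (base_a(rid) if chain == "A"
                    else pos_b.get(rid, base_b_far(rid)))
            out[a] = base if names[a] == "CA" else base + offset
        return out

    all_formed = set(range(len(plan)))
    structure = Structure(
        atom_names=np.array(names, dtype="U5"),
        elements=np.array(elements, dtype="U2"),
        res_ids=np.array(res_ids, dtype=int),
        res_names=np.array(res_names, dtype="U4"),
        chain_ids=np.array(chain_ids, dtype="U4"),
        coords=frame_coords(all_formed))
    trajectory = None
    formed_sets = None
    if frame_plan is not None:
        formed_sets = [set(f) for f in frame_plan]
        coords = np.stack([frame_coords(f) for f in formed_sets])
        trajectory = Trajectory(coords=coords, dt=dt_ps)
    return ToyComplex(structure=structure, plan=plan, trajectory=trajectory,
                      formed_per_frame=formed_sets)


def toy_ensemble(run_frame_plans: Sequence[Sequence[set[int]]],
                 n_res_a: int, n_res_b: int, plan: Sequence[PlannedPair],
                 dt_ps: float = 10.0) -> tuple[Structure, TrajectoryEnsemble]:
    """Build several scripted runs over the same toy complex."""
    structure = None
    runs = []
    for frame_plan in run_frame_plans:
        toy = build_toy_complex(n_res_a, n_res_b, plan, frame_plan, dt_ps)
        structure = toy.structure
        runs.append(toy.trajectory)
    return structure, TrajectoryEnsemble(runs=runs)


# ---------------------------------------------------------------------------
# Replica-exchange helper
# ---------------------------------------------------------------------------

def temperature_ladder(n_replicas: int = 16, t_min: float = 270.0,
                       t_max: float = 500.0) -> np.ndarray:
    """Exponentially (geometrically) spaced replica temperatures in K."""
    if n_replicas < 2 or t_min <= 0 or t_max <= t_min:
        raise ValidationError("need n >= 2 and 0 < t_min < t_max")
    return t_min * (t_max / t_min) ** (np.arange(n_replicas)
                                       / (n_replicas - 1))
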