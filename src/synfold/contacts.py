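"""Native-contact identification, contact-fraction series and salt bridges.

Native contacts are residue pairs whose minimal heavy-atom distance in a
reference structure is below an identification cutoff (4.2 A by
default).  In a trajectory frame a native contact counts as formed when
the same minimal distance is no greater than a slightly looser formation
cutoff (4.5 A by default), so the reference structure itself always has
every native contact formed.  The fraction of formed native contacts of
a class — intermolecular (Q_inter) or tertiary intramolecular per chain
(Q_NCBD, Q_ACTR) — tracks unbinding and unfolding progress.

Salt bridges use residue-specific criteria: an Arg-Asp/Glu pair is in
contact when the side-chain carboxylate carbon to Arg CZ distance is
no greater than 5 A; a Lys-Asp/Glu pair when the carboxylate carbon to
Lys NZ distance is no greater than 4 A.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structure import (BACKBONE_ATOMS, CAP_RESIDUES, Structure, Trajectory,
                        TrajectoryEnsemble)

#: default identification cutoff (A) for native contacts
IDENTIFICATION_CUTOFF = 4.2
#: default formation cutoff (A) in trajectory frames
FORMATION_CUTOFF = 4.5
#: minimum |i-j| for an intramolecular pair to count as "tertiary"
MIN_SEPARATION = 5

INTERMOLECULAR = "inter"


def intra_label(chain: str) -> str:
    return f"intra:{chain}"


@dataclasses.dataclass(frozen=True)
class Contact:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    kind: str  # INTERMOLECULAR or intra_label(chain)


@dataclasses.dataclass
class ContactSet:
    """Labeled native-contact list with the cutoffs that defined it."""

    pairs: list[Contact]
    identification_cutoff: float
    formation_cutoff: float
    min_separation: int
    atom_mode: str  # "all-heavy" or "side-chain-heavy"

    def __post_init__(self) -> None:
        if not self.identification_cutoff < self.formation_cutoff:
            raise ValidationError(
                "identification cutoff must be below the formation cutoff")
        seen = set()
        for c in self.pairs:
            key = frozenset([(c.chain_a, c.res_a), (c.chain_b, c.res_b)])
            if key in seen:
                raise ValidationError(f"duplicate contact pair {c}")
            seen.add(key)

    def by_class(self, kind: str) -> list[Contact]:
        return [c for c in self.pairs if c.kind == kind]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.pairs:
            out[c.kind] = out.get(c.kind, 0) + 1
        return out


@dataclasses.dataclass
class ContactFractionSeries:
    """Per-run fraction of formed native contacts of one class."""

    times: np.ndarray  # ps
    fractions: np.ndarray  # (n_runs, n_frames) or (n_frames,)
    kind: str

    def mean(self) -> np.ndarray:
        q = np.atleast_2d(self.fractions)
        return q.mean(axis=0)


def _residue_atom_groups(structure: Structure, atom_mode: str
                         ) -> list[tuple[str, int, np.ndarray]]:
    """Heavy-atom indices per residue under the requested atom mode.

    Caps are excluded entirely.  Under side-chain mode, glycine falls
    back to its CA so no residue ends up with an empty atom set.
    """
    if atom_mode not in ("all-heavy", "side-chain-heavy"):
        raise ValidationError(f"unknown atom mode {atom_mode!r}")
    heavy = structure.heavy_mask()
    groups = []
    for chain, res_id, res_name, idx in structure.residue_table():
        if res_name in CAP_RESIDUES:
            continue
        sub = idx[heavy[idx]]
        if atom_mode == "side-chain-heavy":
            names = structure.atom_names[sub].astype(str)
            sc = sub[~np.isin(names, list(BACKBONE_ATOMS))]
            if sc.size == 0:  # Gly: CA stands in for the side chain
                sc = sub[names == "CA"]
            sub = sc
        if sub.size == 0:
            continue
        groups.append((chain, res_id, sub))
    return groups


def identify_native_contacts(reference: Structure,
                             cutoff: float = IDENTIFICATION_CUTOFF,
                             atom_mode: str = "all-heavy",
                             min_separation: int = MIN_SEPARATION,
                             formation_cutoff: float = FORMATION_CUTOFF,
                             ) -> ContactSet:
    """Identify native contacts by minimal heavy-atom distance.

    Pairs are classified as intermolecular (different chains) or
    intramolecular per chain; intramolecular pairs must satisfy
    ``|i - j| >= min_separation`` to count as tertiary.  Output order is
    deterministic (sorted by chain and residue numbers).
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    if formation_cutoff <= cutoff:
        # keep the nesting invariant for non-default identification cutoffs
        formation_cutoff = cutoff + (FORMATION_CUTOFF - IDENTIFICATION_CUTOFF)
    groups = _residue_atom_groups(reference, atom_mode)
    if len(groups) < 2:
        raise ValidationError("reference must contain at least two residues")
    # map each heavy atom to its residue group, then find close atom pairs
    atom_idx = np.concatenate([g[2] for g in groups])
    owner = np.concatenate([
        np.full(g[2].size, gi, dtype=int) for gi, g in enumerate(groups)])
    tree = cKDTree(reference.coords[atom_idx])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contact_keys: set[tuple[int, int]] = set()
    for a, b in pairs:
        ga, gb = owner[a], owner[b]
        if ga != gb:
            contact_keys.add((min(ga, gb), max(ga, gb)))
    contacts: list[Contact] = []
    for ga, gb in sorted(contact_keys):
        ca, ra, _ = groups[ga]
        cb, rb, _ = groups[gb]
        if ca == cb:
            if abs(ra - rb) < min_separation:
                continue
            kind = intra_label(ca)
        else:
            kind = INTERMOLECULAR
        if (ca, ra) > (cb, rb):
            ca, ra, cb, rb = cb, rb, ca, ra
        contacts.append(Contact(ca, ra, cb, rb, kind))
    contacts.sort(key=lambda c: (c.chain_a, c.res_a, c.chain_b, c.res_b))
    return ContactSet(pairs=contacts, identification_cutoff=cutoff,
                      formation_cutoff=formation_cutoff,
                      min_separation=min_separation, atom_mode=atom_mode)


def _pair_atom_indices(structure: Structure, contacts: Sequence[Contact],
                       atom_mode: str) -> list[tuple[np.ndarray, np.ndarray]]:
    lookup = {(c, r): sub for c, r, sub in
              _residue_atom_groups(structure, atom_mode)}
    out = []
    for c in contacts:
        try:
            ia = lookup[(c.chain_a, c.res_a)]
            ib = lookup[(c.chain_b, c.res_b)]
        except KeyError as exc:
            raise ValidationError(
                f"contact residue {exc.args[0]} not found in structure") from exc
        out.append((ia, ib))
    return out


def _min_pair_distances(coords: np.ndarray,
                        pair_atoms: list[tuple[np.ndarray, np.ndarray]]
                        ) -> np.ndarray:
    """Minimal inter-residue distance per pair, per frame: (n_frames, n_pairs)."""
    n_frames = coords.shape[0]
    out = np.empty((n_frames, len(pair_atoms)))
    for p, (ia, ib) in enumerate(pair_atoms):
        diff = coords[:, ia, None, :] - coords[:, None, ib, :]
        d2 = np.einsum("fijk,fijk->fij", diff, diff)
        out[:, p] = np.sqrt(d2.reshape(n_frames, -1).min(axis=1))
    return out


def contact_fraction_series(run: Trajectory, structure: Structure,
                            contacts: ContactSet, kind: str,
                            formation_cutoff: float | None = None,
                            atom_mode: str | None = None,
                            ) -> ContactFractionSeries:
    """Per-frame fraction of formed native contacts of one class.

    ``Q(t)`` = (number of native pairs of the class whose minimal
    heavy-atom distance is within the formation cutoff in frame t)
    divided by the class size.
    """
    pairs = contacts.by_class(kind)
    if not pairs:
        raise ValidationError(
            f"contact class {kind!r} is empty (available: "
            f"{sorted(contacts.counts())})")
    cutoff = (formation_cutoff if formation_cutoff is not None
              else contacts.formation_cutoff)
    mode = atom_mode if atom_mode is not None else contacts.atom_mode
    pair_atoms = _pair_atom_indices(structure, pairs, mode)
    dists = _min_pair_distances(run.coords, pair_atoms)
    q = (dists <= cutoff).mean(axis=1)
    return ContactFractionSeries(times=run.times, fractions=q, kind=kind)


def ensemble_contact_fractions(ensemble: TrajectoryEnsemble,
                               structure: Structure, contacts: ContactSet,
                               kind: str,
                               formation_cutoff: float | None = None,
                               ) -> ContactFractionSeries:
    """Stack per-run Q(t) series over an ensemble of runs."""
    series = [contact_fraction_series(run, structure, contacts, kind,
                                      formation_cutoff)
              for run in ensemble.runs]
    return ContactFractionSeries(
        times=series[0].times,
        fractions=np.stack([s.fractions for s in series]),
        kind=kind)


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

#: criterion atom and cutoff (A) per basic residue
_BASIC_CRITERIA = {"ARG": ("CZ", 5.0), "LYS": ("NZ", 4.0)}
#: side-chain carboxylate carbon per acidic residue
_ACID_ATOMS = {"ASP": "CG", "GLU": "CD"}


@dataclasses.dataclass(frozen=True)
class SaltBridgePair:
    """A basic (Arg/Lys) - acidic (Asp/Glu) residue pair."""

    basic_chain: str
    basic_res: int
    acid_chain: str
    acid_res: int

    def label(self) -> str:
        return (f"{self.basic_chain}{self.basic_res}-"
                f"{self.acid_chain}{self.acid_res}")


def _criterion_atoms(structure: Structure, pair: SaltBridgePair
                     ) -> tuple[int, int, float]:
    table = {(c, r): (name, idx) for c, r, name, idx in
             structure.residue_table()}
    try:
        basic_name, basic_idx = table[(pair.basic_chain, pair.basic_res)]
        acid_name, acid_idx = table[(pair.acid_chain, pair.acid_res)]
    except KeyError as exc:
        raise ValidationError(f"salt-bridge residue {exc.args[0]} missing") from exc
    if basic_name not in _BASIC_CRITERIA:
        raise ValidationError(
            f"residue {pair.basic_chain}{pair.basic_res} ({basic_name}) is "
            "not Arg or Lys")
    if acid_name not in _ACID_ATOMS:
        raise ValidationError(
            f"residue {pair.acid_chain}{pair.acid_res} ({acid_name}) is "
            "not Asp or Glu")
    atom_b, cutoff = _BASIC_CRITERIA[basic_name]
    atom_a = _ACID_ATOMS[acid_name]
    names = structure.atom_names.astype(str)
    ib = basic_idx[names[basic_idx] == atom_b]
    ia = acid_idx[names[acid_idx] == atom_a]
    if ib.size != 1 or ia.size != 1:
        missing = atom_b if ib.size != 1 else atom_a
        raise ValidationError(
            f"criterion atom {missing} missing in residue of pair "
            f"{pair.label()}")
    return int(ib[0]), int(ia[0]), cutoff


def salt_bridge_series(run: Trajectory, structure: Structure,
                       pairs: Sequence[SaltBridgePair]) -> dict[str, np.ndarray]:
    """Per-frame formation booleans for each salt-bridge pair."""
    out: dict[str, np.ndarray] = {}
    for pair in pairs:
        ib, ia, cutoff = _criterion_atoms(structure, pair)
        d = np.linalg.norm(run.coords[:, ib] - run.coords[:, ia], axis=1)
        out[pair.label()] = d <= cutoff
    return out


def salt_bridge_probability(ensemble: TrajectoryEnsemble, structure: Structure,
                            pairs: Sequence[SaltBridgePair]
                            ) -> dict[str, np.ndarray]:
    """Ensemble-average formation probability trace per salt-bridge pair."""
    traces: dict[str, list[np.ndarray]] = {p.label(): [] for p in pairs}
    for run in ensemble.runs:
        series = salt_bridge_series(run, structure, pairs)
        for label, formed in series.items():
            traces[label].append(formed.astype(float))
    return {label: np.mean(np.stack(arrs), axis=0)
            for label, arrs in traces.items()}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_contacts(contacts: ContactSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# identification_cutoff_angstrom={contacts.identification_cutoff}"
                 f" formation_cutoff_angstrom={contacts.formation_cutoff}"
                 f" min_separation={contacts.min_separation}"
                 f" atom_mode={contacts.atom_mode}\n")
        fh.write("chain_a\tres_a\tchain_b\tres_b\tclass\n")
        for c in contacts.pairs:
            fh.write(f"{c.chain_a}\t{c.res_a}\t{c.chain_b}\t{c.res_b}\t{c.kind}\n")


def read_contacts(path: str) -> ContactSet:
    meta = {"identification_cutoff_angstrom": IDENTIFICATION_CUTOFF,
            "formation_cutoff_angstrom": FORMATION_CUTOFF,
            "min_separation": MIN_SEPARATION, "atom_mode": "all-heavy"}
    pairs: list[Contact] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            if line.startswith("chain_a"):
                continue
            ca, ra, cb, rb, kind = line.split("\t")
            pairs.append(Contact(ca, int(ra), cb, int(rb), kind))
    return ContactSet(
        pairs=pairs,
        identification_cutoff=float(meta["identification_cutoff_angstrom"]),
        formation_cutoff=float(meta["formation_cutoff_angstrom"]),
        min_separation=int(meta["min_separation"]),
        atom_mode=str(meta["atom_mode"]))
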