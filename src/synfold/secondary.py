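"""Backbone hydrogen-bond based helicity.

A residue i is marked helical in a frame when the i -> i+4 backbone
hydrogen bond (carbonyl O of residue i to amide N of residue i+4) is
within ``HBOND_CUTOFF`` and the bond belongs to a run of at least
``MIN_RUN`` consecutive bonded residues.  Segment helicity is the mean
indicator over the member residues; the overall helicity of a chain
(alpha_NCBD, alpha_ACTR) averages over all its helical-segment residues.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .structure import CAP_RESIDUES, Structure, Trajectory, TrajectoryEnsemble

#: O_i - N_{i+4} distance cutoff (A) for an alpha-helical hydrogen bond
HBOND_CUTOFF = 3.5
#: minimum number of consecutive i -> i+4 bonds to call a run helical
MIN_RUN = 3


@dataclasses.dataclass(frozen=True)
class HelixSegment:
    """A labeled helical segment: chain id plus inclusive residue range."""

    chain: str
    start: int
    stop: int
    label: str = ""

    def residues(self) -> range:
        return range(self.start, self.stop + 1)


#: helical segments of the NCBD/ACTR complex (author numbering):
#: NCBD helices C-alpha-1..3, ACTR helices A-alpha-1..3
NCBD_SEGMENTS = (
    HelixSegment("A", 2067, 2076, "Calpha1"),
    HelixSegment("A", 2086, 2091, "Calpha2"),
    HelixSegment("A", 2095, 2110, "Calpha3"),
)
ACTR_SEGMENTS = (
    HelixSegment("B", 1044, 1058, "Aalpha1"),
    HelixSegment("B", 1063, 1071, "Aalpha2"),
    HelixSegment("B", 1072, 1080, "Aalpha3"),
)


@dataclasses.dataclass
class HelicitySeries:
    """Per-residue helical indicators per frame for one chain."""

    res_ids: np.ndarray  # (n_res,)
    indicators: np.ndarray  # (n_frames, n_res) boolean
    times: np.ndarray  # ps

    def profile(self) -> np.ndarray:
        """Per-residue mean helicity over frames (values in [0, 1])."""
        return self.indicators.mean(axis=0)

    def segment_trace(self, residues: Sequence[int]) -> np.ndarray:
        """Per-frame mean helicity over the given residues."""
        mask = np.isin(self.res_ids, list(residues))
        if not mask.any():
            raise ValidationError("segment residues not present in series")
        return self.indicators[:, mask].mean(axis=1)


def _chain_backbone(structure: Structure, chain: str
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordered residue ids plus O and N atom indices for one chain."""
    res_ids, o_idx, n_idx = [], [], []
    names = structure.atom_names.astype(str)
    for ch, rid, rname, idx in structure.residue_table():
        if ch != chain or rname in CAP_RESIDUES:
            continue
        o = idx[names[idx] == "O"]
        n = idx[names[idx] == "N"]
        if o.size != 1 or n.size != 1:
            raise ValidationError(
                f"residue {chain}{rid} lacks unique backbone N/O atoms")
        res_ids.append(rid)
        o_idx.append(int(o[0]))
        n_idx.append(int(n[0]))
    if not res_ids:
        raise ValidationError(f"chain {chain!r} has no residues")
    return np.asarray(res_ids), np.asarray(o_idx), np.asarray(n_idx)


def residue_helicity(run: Trajectory, structure: Structure, chain: str,
                     hbond_cutoff: float = HBOND_CUTOFF,
                     min_run: int = MIN_RUN) -> HelicitySeries:
    """Per-frame, per-residue helical indicators for one chain."""
    res_ids, o_idx, n_idx = _chain_backbone(structure, chain)
    n_res = res_ids.size
    indicators = np.zeros((run.n_frames, n_res), dtype=bool)
    if n_res < 5:
        warnings.warn(f"chain {chain!r} has fewer than 5 residues; "
                      "helicity is zero everywhere")
        return HelicitySeries(res_ids, indicators, run.times)
    # i -> i+4 bonds only between sequence-consecutive residues
    donor_ok = res_ids[4:] - res_ids[:-4] == 4
    o = run.coords[:, o_idx[:-4], :]
    n = run.coords[:, n_idx[4:], :]
    bonded = (np.linalg.norm(o - n, axis=2) <= hbond_cutoff) & donor_ok
    # keep only bonds inside runs of >= min_run consecutive bonded residues
    for f in range(run.n_frames):
        row = bonded[f]
        i = 0
        while i < row.size:
            if row[i]:
                j = i
                while j < row.size and row[j]:
                    j += 1
                if j - i >= min_run:
                    indicators[f, i:j] = True
                i = j
            else:
                i += 1
    return HelicitySeries(res_ids, indicators, run.times)


def ensemble_helicity_profile(ensemble: TrajectoryEnsemble,
                              structure: Structure, chain: str,
                              hbond_cutoff: float = HBOND_CUTOFF,
                              min_run: int = MIN_RUN
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue helicity averaged over all frames of all runs."""
    total = None
    n_frames = 0
    res_ids = None
    for run in ensemble.runs:
        series = residue_helicity(run, structure, chain, hbond_cutoff, min_run)
        counts = series.indicators.sum(axis=0).astype(float)
        total = counts if total is None else total + counts
        n_frames += run.n_frames
        res_ids = series.res_ids
    return res_ids, total / n_frames


def segment_helicity_trace(run: Trajectory, structure: Structure,
                           segments: Sequence[HelixSegment],
                           hbond_cutoff: float = HBOND_CUTOFF,
                           min_run: int = MIN_RUN) -> np.ndarray:
    """Per-frame helicity averaged over all residues of the given segments.

    With a chain's full set of helical segments this is the overall
    helicity trace of that chain (alpha_NCBD / alpha_ACTR).
    """
    chains = {s.chain for s in segments}
    traces = []
    weights = []
    for chain in sorted(chains):
        series = residue_helicity(run, structure, chain, hbond_cutoff, min_run)
        residues: list[int] = []
        for seg in segments:
            if seg.chain == chain:
                residues.extend(seg.residues())
        mask = np.isin(series.res_ids, residues)
        if not mask.any():
            raise ValidationError(
                f"no segment residues found in chain {chain!r}")
        traces.append(series.indicators[:, mask].sum(axis=1).astype(float))
        weights.append(int(mask.sum()))
    return np.sum(traces, axis=0) / float(sum(weights))
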