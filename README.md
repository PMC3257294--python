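# synfold

Trajectory analysis for the coupled binding and folding ("synergistic
folding") of intrinsically disordered proteins (IDPs).

When two IDPs such as the nuclear co-activator binding domain of CBP
(NCBD) and the activation domain of the p160 coactivator (ACTR) fold
only upon binding each other, the mechanism is dissected by running
ensembles of independent high-temperature unfolding/unbinding
simulations and asking which interactions break first.  `synfold`
implements the full analysis layer of that workflow — everything
downstream of the molecular dynamics itself:

- **Native contacts** — residue pairs within a 4.2 Å minimal heavy-atom
  distance in the reference complex, split into intermolecular and
  per-chain tertiary intramolecular classes; per-frame formation
  fractions `Q_inter`, `Q_NCBD`, `Q_ACTR` (formation cutoff 4.5 Å).
- **Kinetics** — single-exponential fits `A·exp(−t/τ) + B` of
  ensemble-averaged contact fractions and helicities, with the Pearson
  correlation `R` between fit and data as the quality measure, and
  pseudo free-energy surfaces `F(Q_inter, Q_NCBD) = −kT ln p` from early
  non-equilibrium statistics.
- **Helicity** — per-residue α-helicity from the i→i+4 backbone
  hydrogen-bonding pattern (O_i–N_{i+4} ≤ 3.5 Å in runs of ≥ 3 bonds).
- **Helix orientation** — helix axes from the bisector (quadruplet)
  construction, least-squares rigid superposition, and inter-helix
  orientation free-energy surfaces over (φ, θ) with the sin θ Jacobian
  divided out so that isotropic packing is flat.
- **Clustering** — radius-based K-means over mutual Cα RMSD (3.0 Å
  radius convention) with populations and centroid structures.
- **Ensemble observables** — radius of gyration, RMSF after optimal
  superposition, and centered running averages (e.g. 50 ps smoothing).
- **Umbrella sampling / WHAM** — the weighted histogram analysis method
  for 1D potentials of mean force, with a first/second-half convergence
  diagnostic in kcal/mol.
- **Synthetic data** — generators that emulate every input with known
  ground truth: two-state Markov contact ensembles whose mean is exactly
  `B + A·exp(−t/τ)`, ideal helical backbones at programmed orientations,
  Metropolis umbrella samples of analytic potentials, and toy two-chain
  complexes with scripted contact/salt-bridge trajectories.  This makes
  the whole pipeline testable without running MD.

Structures are read from PDB (author numbering preserved), trajectories
from multi-model PDB, binary DCD, or a plain-text XYZ fixture format.

## Worked example

`examples/contact_kinetics.py` builds a synthetic ensemble of 50
independent unbinding runs (62 intermolecular contacts, 10 ns at 10 ps
frames) parameterized by τ = 1.61 ns, A = 0.23, B = 0.17, averages the
per-run contact fractions and fits the exponential:

```
generating constants: tau = 1.61 ns, A = 0.23, B = 0.17
fitted constants:     tau = 1.66 ns, A = 0.23, B = 0.17, R = 0.997
```

τ is the unbinding relaxation time, B the plateau of persistent
contacts, and R the fit–data correlation; a single 50-run ensemble
carries roughly 8–10% statistical spread in τ, so the 3% deviation here
is well within expectation.  The other scripts in `examples/` cover
native-contact identification and salt bridges, helix-orientation
recovery and surfaces, WHAM recovery of an analytic potential, and
ensemble clustering — each prints the numbers it computes and what they
mean.

A thin command-line interface mirrors the library
(`synfold contacts|helicity|orient|ensemble|cluster|kinetics-fit|wham|synth|run`);
`synfold run --config config.yaml` executes configured stages
deterministically and writes a manifest with the config hash.

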