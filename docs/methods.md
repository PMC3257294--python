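# Methods

This note documents the models, conventions and numerical choices behind
`synfold`, in the order a user meets them.

## Native contacts and formation fractions

A native contact is an unordered residue pair whose minimal heavy-atom
distance in the reference structure is at most the identification cutoff
(default 4.2 Å).  Two atom modes exist because both conventions are in
use: `all-heavy` (default for identification) and `side-chain-heavy`,
where glycine's Cα stands in for its absent side chain.  Pairs are
classified intermolecular or intramolecular per chain; intramolecular
pairs must satisfy |i−j| ≥ `min_separation` (default 5) to count as
*tertiary* — the smallest separation that excludes the dense i,i+3/i,i+4
contacts of a helix.  Terminal capping groups (ACE/NH2/NME/CT3/NMA) are
excluded throughout: they are simulation constructs, not sequence.

In a trajectory frame a native contact is *formed* when the same minimal
distance is at most the formation cutoff (default 4.5 Å).  Because
4.2 < 4.5, the reference structure always has Q = 1 for every class.
When a non-default identification cutoff at or above 4.5 Å is requested,
the formation cutoff is lifted by the same 0.3 Å margin to preserve that
nesting.  Formation uses the contact set's atom mode unless overridden,
again so the reference-frame invariant holds.

Salt bridges use residue-specific criteria: Arg–Asp/Glu formed when the
side-chain carboxylate carbon (CG of Asp, CD of Glu) to Arg CZ distance
is ≤ 5 Å; Lys–Asp/Glu when the carboxylate carbon to Lys NZ distance is
≤ 4 Å.  Backbone carbonyls are never used — they cannot form these
interactions.

## Helicity

A residue i is helical in a frame when its i→i+4 backbone hydrogen bond
(O_i to N_{i+4}, both residues sequence-consecutive) satisfies a
distance-only criterion of 3.5 Å and the bond lies in a run of at least
3 consecutive bonded residues.  This is deliberately the simplest
criterion that classifies ideal α-helices correctly (an ideal backbone
built at φ = −57°, ψ = −47° has O–N(i+4) ≈ 3.09 Å) and rejects extended
chains; no angular term, and no separate 3₁₀/π classes.  Published
helicity profiles computed with other hydrogen-bond definitions can
therefore be matched only qualitatively.  Segment helicity averages the
indicator over member residues; a chain's overall helicity averages over
all its helical-segment residues.  The built-in segment table for the
NCBD/ACTR complex uses author numbering (NCBD 2067–2076, 2086–2091,
2095–2110; ACTR 1044–1058, 1063–1071, 1072–1080).

## Helix axes and orientation surfaces

The helix axis comes from the bisector construction: for each quadruplet
of consecutive Cα atoms the two inner bisectors point toward the local
axis and their cross product gives a local direction; directions are
sign-fixed N→C, averaged, and normalized.  On ideal helices this agrees
with the principal axis of the Cα cloud to well under 2° — noting that
the principal axis itself is only unbiased over whole helical turns.

Superposition is the Kabsch SVD solution constrained to proper rotations
(det +1), so mirror images are never matched by a reflection.

Orientation analysis superposes every frame on the reference segment's
backbone, rotates so the reference segment's axis lies along −z (a frame
whose target is parallel to the reference therefore reports θ = π), and
records the target axis direction as inclination θ ∈ [0, π] from +z and
azimuth φ ∈ [−π, π).  The orientation free-energy surface bins (φ, θ)
(default 18 × 18, i.e. 10° cells — a balance of resolution against bin
occupancy at typical ensemble sizes), divides each bin's probability by
sin θ at the bin center to remove the polar-angle Jacobian, and takes
F = −ln p in kT with the minimum over occupied bins anchored at zero.
Unoccupied bins are masked, never extrapolated.  Note that the anchoring
constant is set by the noisiest occupied bin (often near a pole), so
*flatness* of a surface is meaningful as deviation from the occupied
interior's mean, not as the absolute anchored value.  Energies are in kT
at the analysis temperature (default 305 K); only exported labels depend
on T.

## Kinetics

Ensemble-averaged decays are fitted to `A·exp(−t/τ) + B` over
[fit_start, end], with bounds τ > 0 and A, B ∈ [0, 1], multi-start in
τ₀ ∈ {0.1, 1, 5} ns, and the Pearson correlation R between fitted and
observed values reported as fit quality.  `fit_start` defaults to
0.02 ns, excluding the ultrafast initial burn phase seen in real
unfolding ensembles.

The mean of N independent relaxing two-state contacts is exactly the fit
model, but its noise is serially correlated with the relaxation time
itself (autocorrelation exp(−Δt/τ)).  The default estimator therefore
minimizes AR(1)-whitened residuals, iterating the whitening constant to
self-consistency with the current τ — the efficient least-squares
estimator for this noise, verified to sit at the Cramér–Rao bound for
the 50 × 62-contact reference conditions (relative sd of τ ≈ 8%).
`noise_model="iid"` gives the plain unweighted fit.  Both are exact on
noiseless input.  A constant trace has no identifiable τ and is returned
flagged rather than raising.  A double-exponential model is provided but
averaged unfolding traces rarely constrain it; treat it as exploratory.

Intrinsic spread matters when judging recovery: fitting one
50-run ensemble of 30 contacts over 10 ns gives a relative τ spread of
~13–16% when τ is 2–3 ns (the observation window is then only 3–5
relaxation times).  Tests of recovery therefore average over 20 seeded
replicate ensembles; a single-ensemble fit landing 10–15% off is an
expected draw, not a defect.

Pseudo free-energy surfaces Boltzmann-invert the 2D histogram of pooled
(Q_inter, Q_NCBD) samples (default 25 × 25 over [0,1]²), minimum
anchored at zero, unoccupied bins masked.  Built from non-equilibrium
early-window statistics, they are qualitative maps of basins and are
labeled non-equilibrium in the result type.

## Umbrella sampling and WHAM

`wham_solve` iterates the standard self-consistent equations on a
uniform grid (default bin width 0.1 Å, small against the 0.5 Å window
spacing) until the window free-energy constants move by less than
1e−7 kcal/mol (max 10⁵ iterations), then returns −kT ln p with the
minimum at zero, defined only on occupied bins.  kT uses 300 K by
default.  Adjacent windows must share at least one occupied bin; the
error names the gap.  No radial Jacobian correction is applied to
center-of-mass separation coordinates — the coordinate is treated
literally as 1D.

The convergence diagnostic solves WHAM separately on the first and
second halves of every window's samples on a shared grid and reports the
maximum absolute PMF difference after anchoring both minima, restricted
to bins with at least `min_count` (default 100) counts in each half:
a bin with fewer counts carries > 0.06 kcal/mol of shot noise per half
and measures statistics, not convergence.  At 4000 well-decorrelated
samples per window the diagnostic sits near 0.1–0.2 kcal/mol — the
shot-noise floor of a max-abs statistic over ~40 bins — and shrinks with
more data.

## Clustering

`kmeans_radius_cluster` follows kclust-style semantics: the first frame
seeds cluster 1; a frame farther than the radius from every centroid
seeds a new cluster; assignments iterate to a fixed point (max 100
iterations) with centroids recomputed as coordinate means of members
superposed onto the current centroid; equidistant frames break ties to
the lower-indexed cluster, making results deterministic for a given
frame order.  Clusters are reported by descending population.  Centroid
structures are raw coordinate averages — no energetic regularization —
so they can be slightly unphysical locally, as coordinate averages of
fluctuating structures always are.

## Synthetic data: what it emulates and what it does not

The generators define the package's test conditions:

- **Contact ensembles** — each contact is an independent two-state
  Markov chain with rates k_on = p_inf/τ, k_off = (1−p_inf)/τ and
  Bernoulli(p₀) initial occupancy, propagated with the exact finite-step
  transition probabilities so the ensemble mean equals
  p_inf + (p₀−p_inf)·exp(−t/τ) at every frame, not only for small steps.
  Defaults (50 runs, dt = 10 ps, 10 ns) mirror realistic unfolding
  campaigns.  Real contacts are neither independent nor two-state — the
  generator validates the estimator chain, not unfolding cooperativity.
- **Helices** — backbones (N, Cα, C, O) built from ideal internal
  coordinates (trans peptide, φ = −57°, ψ = −47°, giving ~1.5 Å rise and
  ~97° twist per residue and exact screw symmetry), rotated to a
  programmed axis, optionally jittered.  `helix_coil_chain` mixes
  helical and fully extended (φ = ψ = 180°) residues.  No side chains
  beyond the minimal atoms toy complexes need.
- **Umbrella samples** — a Metropolis chain per window on
  U(x) + k/2 (x−x₀)², proposal width 2.4·sqrt(kT/k) (≈50% acceptance),
  1000-step burn-in, thinning 10 so retained samples are effectively
  decorrelated; a warning fires below 5% acceptance.
- **Toy complexes** — two chains of two-atom residues (Cα plus one
  side-chain atom, CZ/NZ/CG/CD for charged types) placed so each planned
  pair's criterion-atom distance is exact; scripted frames displace
  unformed partners 100 Å away.  Geometry, not chemistry: these validate
  cutoff logic and bookkeeping.

All randomness flows through one explicitly passed seeded generator; a
fixed seed reproduces every output bit for bit, and the pipeline derives
per-stage seeds from the config seed.

Passing tests on these inputs demonstrates that the analysis operations
are correct and statistically calibrated.  They do not demonstrate that
real unfolding ensembles are single-exponential, that 50 runs suffice
for a given system, or that the helicity criterion matches any
particular MD package's definition.

## Design choices and limitations

- The package is library-first (importable API plus `examples/`); the
  CLI is a thin click layer, and the config-driven pipeline
  (`RunConfig`/`run_pipeline`) orchestrates synthetic-demo stages with a
  manifest (config SHA-256, parameters, outputs) for auditability.
- Residue identity is (chain id, author residue number) exactly as in
  the source PDB; alternate locations resolve to highest occupancy.
- Frame interval dt is required wherever the file format carries no time
  metadata; synthetic writers embed it (XYZ comment line).
- Hydrogens are kept on read but all contact and geometry criteria use
  heavy atoms only.
- Radius of gyration is unweighted by default (mass weighting optional);
  for protein heavy-atom selections the two differ by well under 1%.
- 2D WHAM, MBAR, hierarchical clustering, β-structure classification and
  any force-field or sampling machinery are out of scope.
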