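# Methods

This note records the models and algorithms `pldock` implements, the
defaults it ships, the design decisions that were genuinely open, and what
the synthetic fixtures do and do not demonstrate.

## Scoring function

The conformation-dependent score is the Vina-family empirical potential: a
weighted sum of five closed-form terms of the surface distance
`d = r − (R_a + R_b)` between heavy atoms, cut off at `r = 8 Å`, summed
over all heavy-atom pairs that can move relative to each other.  Pairs
separated by at most three consecutive covalent bonds (1-2, 1-3, 1-4) are
excluded, as are pairs rigidly coupled within one torsion-tree frame
(their distance cannot change, so they would only add a constant).

Term forms and weights:

| term        | form                                  | weight     |
|-------------|---------------------------------------|------------|
| gauss1      | `exp(−(d/0.5)²)`                      | −0.035579  |
| gauss2      | `exp(−((d−3)/2)²)`                    | −0.005156  |
| repulsion   | `d²` for `d < 0`, else 0              | +0.840245  |
| hydrophobic | 1 for `d ≤ 0.5`, ramp to 0 at 1.5     | −0.035069  |
| hbond       | 1 for `d ≤ −0.7`, ramp to 0 at 0      | −0.587439  |

All distances in Å.  The hydrophobic term applies only when both atoms are
hydrophobic; the hydrogen-bond term only to donor-acceptor pairs.  The
weights are the published regression values of the Vina family, which this
engine inherits; they are config-overridable (`ScoringWeights`), as the
potential's exact coefficients are calibration artifacts, not structural
constants.

### Atom typing

Fifteen heavy-atom functional types: hydrophobic carbon, polar carbon
(bonded to N or O), four nitrogen variants (plain, donor, acceptor,
donor-acceptor), two oxygen variants (acceptor, donor-acceptor), S, P, F,
Cl, Br, I, and metal.  Metal ions are treated as hydrogen-bond donors.
Halogens count as hydrophobic.  Van der Waals radii: C 1.9, N 1.8, O 1.7,
S 2.0, P 2.1, F 1.5, Cl 1.8, Br 2.0, I 2.2, metal 1.2 Å.  Donor character
is read from the polar hydrogens (`HD`) the PDBQT input carries; since
PDBQT has no bond records inside rigid frames, covalent connectivity —
needed for polar-carbon typing, 1-4 exclusions, and hydrogen-only torsion
detection — is perceived geometrically (`r < 1.15 (r_cov,a + r_cov,b)`).
Hydrogens are kept for typing but never scored.

### Precalculation

Every pair curve (120 unordered type pairs) is sampled at 16,384 points
uniformly in `r` over [0, 8 Å], alongside its analytic `d/dr` derivative;
reads take the nearest sample with no interpolation.  Sampling uniform in
`r` (rather than `r²`) was an open choice; uniform-in-`r` keeps the bin
width, and hence the lookup error bound `L·Δr`, constant across the range.

Inter-molecular energies are additionally precalculated on a cubic lattice
over the search box (default granularity 0.15625 Å, user-adjustable), one
value lattice plus three gradient lattices per ligand atom type, built
lazily for the types a ligand actually contains and cached per
(receptor, box, granularity, weights).  Lattice reads also take the
nearest node.  Conformations that stray outside the box are clamped to it
rather than rejected, keeping the optimizer inside the feasible region.

### Output free energy

The top conformation's intra-molecular score is subtracted from each
conformation's total and the difference divided by
`1 + w_flex (N_active + ½ N_inactive)` with `w_flex = 0.05846`.
Subtracting a per-ligand constant and dividing by a per-ligand constant
preserves the within-ligand ranking by construction.  Giving inactive
torsions half weight was an open choice: they exist as rotors but cannot
move heavy atoms, so they are penalized less than active ones.

Conversions: `pKd = −ΔG / (RT ln 10)` with `R = 1.9872×10⁻³ kcal/(mol·K)`
and `T = 298.15 K`; ligand efficiency `ΔG / N_heavy`; consensus score
= arithmetic mean of the engine's pKd and the forest's pKd.  Putative
hydrogen bonds are reported for donor-acceptor heavy-atom pairs within
3.5 Å; angle criteria are deliberately omitted because hydrogen positions
in PDBQT input are unreliable.

## Search

Pose variables: root-frame position, orientation quaternion, one angle
per active torsion.  Forward kinematics transforms the root rigidly, then
rotates each branch frame about its (already transformed) rotor axis,
depth-first.

Independent Monte-Carlo chains (default 64; chain `c` seeds its own
generator with `seed + c`, so results are independent of execution order)
each run `iterations_base · (1 + N_heavy/32 + N_active/4)` iterations of
(mutate → BFGS local optimization → Metropolis acceptance at temperature
1.2 score units).  A mutation perturbs exactly one degree-of-freedom
class: position (uniform in a 2 Å ball), orientation (random axis, angle
uniform on (0, π)), or one torsion (resampled uniformly).  The full-range
orientation move is a deliberate choice: each proposal is followed by
local optimization, which repairs poor placements, and near-half-turn
proposals are the only small-step route out of an end-for-end flipped
binding mode — with a small-angle cap, chains that enter a site backwards
stay backwards for the whole run.

BFGS maintains an inverse-Hessian approximation (reset on curvature
breakdown), uses the analytic gradient assembled by torsion-tree
back-propagation of per-atom forces (position gradient = total force;
orientation gradient = torque mapped through the SO(3) exponential-map
Jacobian of the rotation-vector chart; torsion gradient = axis-projected
subtree torque), and stops exactly when the backtracking Armijo line
search (c₁ = 10⁻⁴, halving, 12 trials) finds no acceptable step.

### Candidate refinement and ranking

Nearest-node lookups quantize the landscape at the lattice spacing, so
grid-driven minima can stop up to about a node short of the true optimum
— enough to reorder near-degenerate binding modes.  The final stage
therefore works on the smooth closed forms ("exact" scoring): all pooled
minima are exactly re-scored; the leading distinct candidates get (a) two
deterministic end-over-end flip proposals (half-turns about the axes
perpendicular to the pose's principal axis, each followed by local
optimization and accepted only on exact improvement), (b) a short greedy
basin-hopping walk (default 48 improvement-only mutation+optimization
hops), and (c) an exact-potential BFGS polish.  Poses are then clustered
greedily by RMSD (default 1.0 Å) and at most 9 are returned, ranked by
output free energy.  Everything derives from the run seed, so outputs are
bit-for-bit reproducible.

RMSD is computed on heavy atoms with fixed correspondence and no
superposition (poses share the receptor frame), and no graph-automorphism
symmetry correction.

Defaults not fixed by the method itself (`n_runs = 64`,
`iterations_base = 100`, temperature 1.2, cluster RMSD 1.0 Å) are
config-exposed placeholders validated only by the planted-optimum tests.

## Rescoring forest

Features: counts of protein-ligand element pairs (protein C, N, O, S ×
ligand C, N, O, F, P, S, Cl, Br, I → 36 features) within 12 Å, the
generous cutoff capturing solvation-shell structure implicitly; the
comparison is `≤`.  Elements, not the 15 engine types, define the
features.  The forest is scikit-learn's `RandomForestRegressor`
configured to the protocol: 500 unpruned CART trees on bootstrap samples,
best variance-reducing split among 12 randomly chosen features (~p/3 for
regression), nodes with at most 5 samples become leaves
(`min_samples_split = 6`); the prediction is the mean over trees of the
traversed leaf's training mean.  Models serialize with joblib (config +
fitted trees + training-label range).  Training tables are plain CSV
(id, 36 counts, pkd).

## Synthetic fixtures

`make_funnel_complex` builds the study system for the search tests: a
rigid (optionally flexible) zigzag chain ligand — terminal acceptor
oxygen, then nitrogen, then carbons, 1.4 Å spacing — seated in a surface
pocket assembled from typed PDBQT atoms:

* a double slab of hydrophobic floor carbons at Van der Waals contact
  below the molecular plane (2 Å lattice; the second layer leaves no
  habitable space between the slab's underside and the box wall),
* carbon ridges flanking the full chain, with flared entrance rings,
* a carbon cap and two in-plane donor nitrogens at the buried end, plus
  two donors sunk into the floor beneath the oxygen seat.  The donors
  reward the correctly oriented chain through the hydrogen-bond term and
  punish the end-for-end flip sterically (the flip parks carbon on them).

The nominal geometry is first relaxed to the deepest nearby basin of the
analytic potential (multi-start BFGS) and the ligand replanted at the
relaxed coordinates, so the planted pose is an optimum of the engine's
own potential rather than of the hand-built geometry.  Certification then
scores rigid copies of the ligand on an exhaustive 1 Å translation grid
crossed with eight rotations (identity, three half-turns, quarter-turns),
plus 300 random rigid placements, and BFGS-polishes the most competitive
off-plant probes; if any pose more than 1 Å from the plant comes within
0.2 score units, the build fails (jittered retry), and if polishing finds
a strictly deeper basin anywhere, the ligand is replanted there and
certification restarts.  Fixture construction is deterministic per seed.

What passing the planted-optimum test shows: the full pipeline — typing,
tables, maps, kinematics, gradients, global search, refinement, ranking —
can reliably recover a certified global optimum in a rugged but honest
landscape with decoy minima (flips, registry shifts, surface sites).
What it does not show: performance on real binding sites, whose
desolvation, electrostatics, conformational strain and structural noise
the toy pocket does not emulate; nor search behaviour for highly flexible
ligands (> 10 rotatable bonds), where recovery is expected to degrade.

`make_rf_training_set` emulates the statistical shape the forest assumes:
Poisson contact counts (rates drawn once from U[0.5, 8]) linked to the
label by a sparse linear map (8 informative of 36 features) plus one mild
pairwise interaction and N(0, σ) noise around a pKd-like offset of 5.
It supports recovery tests (held-out Pearson r > 0.9 at n = 500,
σ = 0.1), not claims about real affinity data.

## Problem sizes and study conditions

The bundled tests and the acceptance script run at toy scale, chosen as
the smallest sizes at which every mechanism is exercised: a 5-heavy-atom
rigid ligand in a ~15.6 Å box, grid granularity 0.25 Å for the toy
complexes (the production default stays 0.15625 Å), redocking repeated
over 20 seeds at 16 chains × ~58 iterations, forest training at
n = 400/100 train/test.  Success is pose-1 RMSD < 1.0 Å against the
certified plant.

## Numerical notes and limitations

* The truncated potential is discontinuous at the 8 Å cutoff (the curve
  value just below it is small but nonzero); gradient checks therefore
  exclude pair distances on the cutoff, and so should any user-side
  finite-difference validation.
* Nearest-node grid reads make the search landscape piecewise constant at
  the granularity scale; the exact-scoring refinement stage exists
  precisely to remove this quantization from final ranking.  Per-atom
  energies written to output columns 71-76 are inter-molecular only.
* Bond perception is geometric; exotic coordination geometries (e.g.
  metal clusters) may type atoms imperfectly.
* The engine does not model receptor flexibility, solvation,
  electrostatics, or protonation; regression weights are inherited, not
  re-derived.
* `correlation_metrics` reports SD as the standard deviation of
  (predicted − experimental) by default, with a `residual` option for the
  regression-line convention some benchmarks use — both conventions exist
  in the literature and differ slightly.
* The automatic search box reads "extend by 10 Å" as +10 Å on the cube
  edge (5 Å per face), a documented convention switchable via the
  `margin` argument.
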