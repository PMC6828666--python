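# Methods

This note records the models, numerical choices and limitations behind
`openpocket`, in the spirit of a software methods appendix.

## Atom parameterization

Every atom carries a van der Waals radius `w_a` and Lennard-Jones pair
coefficients `(A, B)` in kcal/mol·Åⁿ against an implicit carbon-like probe.
The packaged table (`data/atom_params.tsv`) is element-keyed with a generic
carbon fallback; values are constructed from per-element well depths ε
(0.02–0.35 kcal/mol) and minimum-energy distances `r_min = w_a + 1.7 Å` via
`A = ε·r_min¹²`, `B = 2ε·r_min⁶`, so the single-atom potential has its
minimum −ε exactly at `r_min`.  These are documented implementation
defaults in the ECEPP tradition, not a reproduction of any published force
field; the table format accepts user overrides, including atom-name-keyed
rows that take precedence over element rows.

## Grid maps

All maps live on axis-aligned uniform grids (default 1 Å for potential
maps, 0.5 Å for density maps).  The attraction map is truncated at
−0.8 kcal/mol with values above the threshold set to zero (≤ keeps the
boundary), so only attractive regions survive.  Grid nodes closer than
0.3 Å to an atom centre are clamped to +10⁶ kcal/mol before truncation to
avoid floating-point overflow; truncation always removes them, so the
clamp value never reaches downstream results (an additivity caveat: sums
of per-atom-subset maps differ from the full map only at clamped nodes).

The Gaussian convolution uses the *unnormalized* prefactor `1/λ³`, so a
constant field C maps to `π^(3/2)·C` rather than C.  The discrete
implementation multiplies by the voxel volume h³ and exploits
separability: the 3-D kernel factorizes into identical 1-D kernels applied
per axis (taps below 10⁻¹⁴ truncated), which matches the direct
O(N²) node-pair summation to better than 10⁻⁶ relative (asserted in
tests).  The box boundary is zero-padded.

Maps are serialized as CCP4/MRC volumes (via gemmi, with a plain-text
origin sidecar, since the CCP4 cell starts at zero) or as a portable text
dump used in tests.

## Pocket envelopes and druggability

The detection pipeline is: LJ map → truncation → λ = 2.6 Å smoothing →
isovalue contour → 26-connected components (≥ 10 voxels) → per-envelope
metrics.  Volume is voxel count × h³; principal axis lengths are
`2·sqrt(3·eigenvalue)` of the voxel-coordinate covariance (each voxel
modelled as a cube, adding h²/12 per axis, which makes a single voxel
exactly spherical); sphericity is the smallest-to-largest axis ratio,
bounded in (0, 1] and rotation invariant.

**Contour calibration.**  No principled closed form fixes the contour
level, and it directly sets detected volumes.  The default (−2.5 map
units) was calibrated once against geometric truth: hollow-sphere shells
of cavity radius 3–6 Å (atom centres at radius + w_C, so the van der Waals
surface bounds the cavity) must yield a single envelope whose volume
matches (4/3)πr³.  At −2.5 all tested radii and lattice seeds agree within
±20%; the truncation threshold propagated through the unnormalized
prefactor (−0.8·π^(3/2) ≈ −4.5) was considered and rejected because it
under-detects cavity volume by ~40%.

The druggability verdict is deliberately simple: druggable iff volume in
[150, 800] ų and sphericity ≥ 0.3, all configurable.  The per-model score
(triangular volume score × linear shape score) ranks models but is a
stand-in for expert visual inspection, and reports say so.

## Fumigation

The protocol approximates the largest possible pocket by density, then
pushes side chains out of it:

1. residues with any heavy atom within the pocket radius (default 8 Å) of
   the given centre are selected; those outside {Ala, Gly, Cys} are shaved
   to alanine (atoms beyond CB removed; backbone and CB coordinates
   untouched);
2. the shaved structure's atom density D (0.5 Å grid) is convolved with
   λ = 12 Å to give D_c, which fills cavities; F = D_c − D is the
   repulsive pseudo-ligand density — largest at cavity centres, small
   inside atoms and far away;
3. the *original* side chains are sampled against F.  Whether the original
   protocol sampled restored or shaved chains is ambiguous; sampling the
   full chains is the useful reading (the output must be a real,
   full-atom conformation) and is what this package does.

**Energy model.**  Combined energy = physical + penalty, with
penalty = w_F · Σ F(atom) over selected side-chain heavy atoms (trilinear
interpolation; atoms outside the map contribute 0 with a warning) and
physical = quartic soft clash `10·(d₀−d)⁴` kcal/mol for inter-residue
heavy-atom pairs closer than `d₀ = 0.8·(w_i+w_j)`, plus a 3-fold torsion
term `0.3·(1+cos 3χ)` kcal/mol per χ.  This is a minimal energy: the
design contract is that the penalty map, not the force field, drives
pocket opening.  The default w_F = 3 kcal/mol per density unit makes the
penalty of one buried side chain (F ~ 1–2 per atom, 4–7 atoms) tens of kT
at 300 K — decisive but not move-rejecting.

**Sampling.**  Metropolis over χ torsions: each step picks one residue
uniformly and either perturbs a single random χ by N(0, 15°) (probability
0.7) or redraws all its χ uniformly (otherwise from a configurable
discrete jump set, which also enables exact two-state calibration tests).
Acceptance is min(1, exp(−ΔE/RT)).  Torsion moves rotate the existing
distal atoms about the χ axis, preserving input bond lengths and angles
exactly — the torsion round trip is exact to 10⁻⁶ degrees and the backbone
never moves.  Per-residue energy bookkeeping makes deltas exact (only one
residue moves per step); recorded totals subtract the double-counted
cross-pair clash, and tests assert recorded energies equal a from-scratch
recomputation.  One seeded generator drives the whole run; identical seed
means bit-identical trajectories.

Ranking uses combined energy (including the penalty) by default because
the protocol's goal is open-pocket models; a `physical` criterion is
available.  The top 20 distinct conformers (torsions rounded to 10⁻⁴ °,
ties by acceptance step) are re-scored with the pocket detector; the
per-conformer LJ maps reuse the static-atom contribution since only
sampled side chains move.

## Hit triage

Funnel order: score → clustering → properties → anchor distance → top-N.
Numerical conventions: "score below −30" is read inclusively (≤ −30);
anchor distance is the minimum heavy-atom pair distance between pose and
anchor residue (most permissive reading, ≤ 8 Å passes); drug-like windows
default to MW [150, 550] g/mol, logP [−1, 5], logS ≥ −6 (named properties
with undocumented ranges in the source protocol; these defaults are the
package's).  Clustering is greedy leader clustering, best score first,
joining the first representative with Tanimoto ≥ threshold (default 0.6):
deterministic and O(n·k).  Whether the score cut applies per-model or
best-across-models in multi-model screens is a caller decision; the
filters operate on whatever score column they are given.  The full-atom
score combiner is a pure weighted sum; the α constants are not published
and default to 1, so absolute values are only meaningful with
user-supplied weights.

## Synthetic fixtures

The generators emulate the *geometry* of the problem, not protein
chemistry:

* **hollow sphere** — carbon pseudo-atoms on a Fibonacci lattice at radius
  r + w_C enclosing an empty cavity of radius r; the analytic cavity
  volume is the oracle for pocket detection.  A seed-dependent random
  rotation decorrelates the lattice from the grid.
* **collapsed pocket** — a quasi-spherical wall (pseudo-atoms plus eight
  alanine scaffold residues) with 3–5 lysines seated in wall openings;
  their χ1/χ2 are grid-searched at build time for the most buried pose
  (and, for the open reference, the most exposed one), and wall atoms
  within 3 Å of either pose are removed so both states are sterically
  reachable.  Construction asserts the collapsed tips lie inside the
  cavity and the open tips outside the wall.
* **toy hit table** — scores N(−20, 10), MW U(100, 700), logP N(2.5, 2),
  logS N(−4, 1.5), anchor distances U(2, 15), random 64-bit fingerprints
  with planted duplicates every 10th record.  The N(−20, 10) score model
  makes the −30 cut's survivor count analytically checkable (Φ(−1)).

What passing tests on these fixtures shows: the maps, contouring, sampling
and funnel behave exactly as specified on controlled geometry.  What they
do not show: performance on real proteins — no rotamer statistics, no
backbone plasticity, no real chemistry in fingerprints or properties.  The
one real-structure check (the ~832 Å² CK2α/CK2β interface area from PDB
1jwh) needs that structure to be present or downloadable and is otherwise
reported as unavailable.

## Problem sizes and determinism

Default problem sizes used by the acceptance script: 200-atom shells,
~220-atom collapsed-pocket toys, 10,000 MC steps × 5 seeds, 10,000-row hit
tables, 20,000-step two-state chains — chosen so a full from-scratch rerun
completes in about half a minute on one CPU while leaving the stochastic
acceptance margins wide.  All stochastic components consume a single
integer seed; sub-seeds are derived arithmetically and stay below 2³¹.

## Known limitations

* Backbone conformations are fixed; pockets whose opening requires loop
  movement (as opposed to side-chain rearrangement) stay closed.
* The physical energy has no electrostatics, hydrogen bonding or solvent;
  conformer rankings beyond the penalty-driven ordering are not
  meaningful energetically.
* Hydrogens, if present, ride along only for shaving and output; maps and
  energies are heavy-atom only, and χ rotations do not move side-chain
  hydrogens.
* Envelope volumes inherit ±1 voxel surface uncertainty (~±15–20% for
  300 ų pockets at 1 Å spacing); arbitrary-angle rotation invariance
  holds only to that discretization tolerance.
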