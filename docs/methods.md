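# Methods

This note documents the models, parameter choices and numerical conventions
behind `unfoldmap`, and what the synthetic-data validation does and does not
establish about real trajectories.

## Scope and assumptions

The package analyses an *ordered ensemble* of conformations of one topology —
typically frames of a high-temperature unfolding simulation — together with a
**native pool**: a set of reference frames (e.g. minimization-stage
structures) that defines the folded baseline. It does not simulate dynamics,
compute solvation free energies, or assign secondary structure; per-frame
secondary-structure strings, when the melting percentages are requested, must
be supplied (by the generator or an external assigner such as DSSP). The
trajectories are assumed whole-molecule and unwrapped (implicit-solvent
style); no periodic-boundary handling is attempted.

## Per-frame properties

* **Native contacts (Qsh).** The contact set is all Cα pairs with sequence
  separation ≥ 7 residues and native distance < 10 Å. The default *hard* mode
  counts the fraction of those pairs still closer than the cutoff in the
  query frame. A *soft* variant, mean over pairs of
  1/(1 + exp(β(d<sub>ij</sub> − λ·d<sub>ij</sub><sup>native</sup>))) with
  β = 5 Å⁻¹ and λ = 1.2, is available where a differentiable coordinate is
  preferred; the hard count is the default because it matches the plain
  "fraction of long-range native contacts retained" definition. Hetero atoms
  (ions, cofactors) never enter Cα-based metrics.

* **RMSD / dRMS.** RMSD is the least-squares Cα superposition (proper
  rotations only — a mirror image does not superpose); pairwise RMSD between
  many frames uses a batched Kabsch (3×3 SVDs with sign correction), accurate
  to ~10⁻⁶ Å against the pair-at-a-time route. dRMS is the RMS difference of
  the two Cα–Cα distance matrices and needs no superposition.

* **Solvent-accessible surface area.** Shrake–Rupley with probe 1.4 Å and
  960 test points per atom, the field-standard settings. The point set is a
  fixed golden-spiral construction, so areas are fully deterministic for a
  given point count (a Monte-Carlo point set would make every downstream
  number run-dependent). Van der Waals radii come from a Bondi-like table
  (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) overridable per element or per atom;
  hetero atoms participate as generic spheres (Fe 2.0 Å). Accuracy at 960
  points: < 1 % on an isolated sphere, < 2 % against the analytic two-sphere
  cap formula; an independent Shrake–Rupley (biotite's) agrees within 2 % on
  compact chains.

* **ASA splits.** Side chain = everything outside {N, CA, C, O, OXT}. The
  polar residue class defaults to {D, E, K, R, H, N, Q, S, T, Y, C, W} and is
  a config table, since polar/non-polar conventions vary between labs; the
  partition identities (total = polar + non-polar) hold exactly by
  construction. Named-region selections (e.g. an active-site lumen) aggregate
  per residue list in total or side-chain mode.

* **Secondary-structure melting.** l.H = 100·(H<sub>native</sub> −
  H<sub>frame</sub>)⁺/H<sub>native</sub> and analogously l.E; l.C =
  100·(C<sub>frame</sub> − C<sub>native</sub>)⁺/(L − C<sub>native</sub>).
  Negative "melting" (more structure than native) clamps to zero; empty
  denominators return 0 with a warning rather than NaN.

* **Dipole moment.** |Σ qᵢrᵢ| in Debye (1 e·Å = 4.80320 D) about the
  geometric center for net-neutral systems. For net-charged systems the
  |q|-weighted charge centroid is used as origin: the signed-charge centroid
  would make the moment identically zero, and the |q|-weighted origin keeps
  the number finite and reproducible. Charges are user-supplied (force-field
  or formal); the package assigns none of its own.

* **ΔC<sub>p</sub>.** Linear in the ASA changes relative to the native-pool
  mean: ΔC<sub>p</sub> = a<sub>np</sub>·ΔASA<sub>np</sub> +
  a<sub>p</sub>·ΔASA<sub>p</sub>, defaults a<sub>np</sub> = 0.28,
  a<sub>p</sub> = −0.09 cal mol⁻¹ K⁻¹ Å⁻² (the Myers–Pace–Scholtz
  regression); both coefficients are config.

## The d reaction coordinate

Orientation rules are explicit and logged: properties that grow upon
unfolding (ASA, Rg, RMSD, dRMS, melting percentages, ΔC<sub>p</sub>) enter
as-is, the native-contact fraction is flipped, and signed/region quantities
(dipole moment) enter as absolute deviation from their native-pool mean.
Each oriented column is shifted by its native-pool mean and divided by its
trajectory maximum: the native ensemble maps near 0 and the most deviant
frame to exactly 1; values below the pool mean clamp at 0. Constant columns
are zeroed with a warning and excluded from *N*.

*d* is the root-mean-square of a frame's normalized deviations from the
native-pool mean — RMS rather than a plain sum so the scale of *d* does not
depend on how many properties are configured. By default the series is
renormalized to max = 1, fixing the endpoints *d*(native) = 0 and
*d*(most unfolded) = 1. Duplicating a property column changes *d* only in the
usual RMS sense (d′² = (N·d² + dev²)/(N+1)); adding uninformative columns
shrinks the dynamic range but never moves the zero. The density of *d* is a
Gaussian KDE on [0, 1] (Scott's-rule bandwidth by default, explicit override
available), renormalized to unit integral on the grid.

## State decomposition

PCA is computed on the centered normalized matrix with a deterministic sign
convention (largest-magnitude loading positive). The 2-D KDE of the first two
PC scores is converted to a potential of mean force, PMF = −RT ln ρ, shifted
to min 0; RT defaults to 0.9935 kcal/mol (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹ at
the 500 K analysis temperature) and is config.

Non-metric MDS (Kruskal stress-1, monotone regression; scikit-learn's SMACOF)
embeds the Euclidean distances between normalized property rows in 2-D; four
random restarts, best stress kept, deterministic per seed. Affinity
propagation then clusters the embedding (similarity = negative squared
Euclidean distance, preference = median similarity, damping 0.9); exemplars
are actual frames, and states are reported ordered by mean *d*. Clustering on
the full normalized matrix instead of the embedding is a flag. Two known
behaviors to keep in mind: AP with the median preference over-partitions
*strongly unbalanced* basins (the sub-clusters remain pure subdivisions —
homogeneity stays 1), and frames inside a smooth transition ramp blur
adjacent clusters. Frames may be strided before the O(n²) stages; the stride
is recorded in the outputs.

## Information content

Per property, the per-state mean unfolding fractions are renormalized to sum
to 1 across states (f<sub>oU</sub>) and scored as I = log₂k − H(f<sub>oU</sub>)
bits (nats available); 0 ≤ I ≤ log₂k, I = 0 for a property spread uniformly
over states. The across-*states* renormalization is the essential convention:
it makes I measure how unevenly a property's unfolding is distributed along
the pathway, independent of the property's absolute scale. All-zero columns
get I = 0 with a flag. Cross-run comparison reports each run's percentage of
a property's summed I.

## Transition point

For every (strided) frame *x*, neighbors are all other frames within the
pairwise Cα RMSD cutoff (default 3 Å); the folded fraction is the share of
neighbors with d < d<sub>x</sub> (ties split evenly), the unfolded fraction
its complement. Both curves over the d-sorted evaluation grid are smoothed by
an 11-point running mean; the junction is located by linear interpolation at
the sign change of their difference. All crossings are reported; the one with
the longest surrounding sign-consistent run is labelled the main transition,
and the raw (unsmoothed) crossing is kept alongside. Two guard rails:
evaluation frames with empty neighborhoods are skipped (and counted), and a
trajectory whose *d* never exceeds 0.5 — a single compact basin with no
unfolded side — raises a no-transition error instead of reporting the basin's
internal median. The cutoff can be recalibrated from the data as the mean
native-reference RMSD over frames with |d − 0.5| ≤ 0.05, the same
"half-unfolded structures are ~3 Å from native" logic that motivates the
default. The estimator is sharpest when the coordinate is continuously
populated by two overlapping basins; on trajectories that dwell in widely
separated discrete states the curves cross once per basin and the main
crossing becomes ambiguous (the analysis scripts note this where it occurs).

## Synthetic data: what it emulates, what it does not

The generator builds a compact self-avoiding Cα + pseudo-side-chain chain
(3.8 Å virtual bonds, ≥ 1 long-range contact guaranteed, planted
helix/strand/coil string) and models unfolding as **centroid-anchored
expansion**: coordinates scale about the centroid by a per-state factor ≥ 1,
plus isotropic Gaussian noise; secondary structure melts in proportion to the
expansion. This reproduces exactly the signals the analysis consumes —
breaking long-range contacts, growing Rg/ASA/dRMS, melting planted structure
— while remaining analytically tractable (Rg and RMSD are exactly linear in
the expansion factor). Default study conditions: 40 residues, 400 frames,
four states with dwell fractions 0.15/0.25/0.30/0.30, expansions
1.0/1.3/1.7/2.2 and noise 0.05–0.15 Å — a compact native ensemble, two
metastable intermediates, an expanded unfolded ensemble. All randomness flows
through counter-based per-frame streams: extending a trajectory never
perturbs earlier frames.

The two-basin transition fixture draws planted *d* values from an
equal-weight Gaussian mixture symmetric about the target crossover
(components at d* ± 0.20, sd 0.15, observation noise 0.03) and realises them
geometrically, with the expansion range set so the native→(d = 0.5) RMSD is
3 Å — the same calibration that justifies the 3 Å neighbor cutoff. Its *d* is
built from the expansion-linear properties (RMSD, dRMS, Rg), because a
planted crossover is only meaningful when the computed coordinate is linear
in the planted one (the contact fraction saturates early and would warp the
scale).

What passing on these fixtures shows: the pipeline's arithmetic, orientation
and normalization conventions, clustering stack and junction estimator are
correct and recover planted structure under realistic noise. What it does not
show: behavior on real unfolding ensembles, where properties decorrelate
(expansion makes them all nearly collinear here — hence the very high PC1
variance on synthetic runs), states differ by topology rather than size, and
the native pool has genuine internal diversity.

## Numerical conventions and edge cases

Residues are 1-based (PDB convention), frames 0-based everywhere. PDB I/O
round-trips coordinates to the format's 10⁻³ Å precision. Normalization
clamps to [0, 1]; zero-variance columns drop from *N* with a warning;
all-identical inputs to affinity propagation collapse to one cluster with the
lowest index as exemplar; non-convergent AP returns its best labeling flagged
non-converged. KDE on a degenerate (constant) *d* series returns a flagged
single spike. Pipeline outputs are a pure function of (config, seed): floats
are rounded to 10 significant decimals before JSON serialization so re-runs
are byte-identical. Logging at INFO records every default the user did not
set.

## Problem sizes

The shipped configurations are sized for interactive use on one CPU: default
pipeline runs use 120–400 frames of 20–40-residue chains (SASA at 960 points
dominates, a few milliseconds per frame), and the transition analysis
evaluates ≤ 400 grid frames against ≤ 2000 frames via the batched pairwise
RMSD. The O(n²) state/transition stages expose a stride knob for longer
trajectories.
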