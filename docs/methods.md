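# Methods

`foldpath` predicts a protein's folding *pathway* — the order in which
regions of the chain reach their native arrangement — from the structural
record of its evolutionary family. The premise: regions that are
structurally conserved across remote homologs are the regions that fold
first. The package turns that premise into a concrete simulation: a
conservation profile extracted from a multiple structure alignment (MSTA)
parameterizes a statistical restraint potential and a fragment library,
and a three-stage Monte Carlo fragment-assembly run produces a trajectory
of transition states, intermediates and a final state.

## Conservation profile (F values)

Each homolog in the MSTA is superposed onto the target with a
TM-score-optimal (inlier-weighted, iteratively refined Kabsch)
superposition. For target residue *i* and homolog *n*, the CA–CA deviation
d_i maps to a binned score:

    sco_n(i) = 1     if d_i <= 2 A
             = 0.75  if 2 < d_i <= 4 A
             = 0.25  if 4 < d_i <= 5 A
             = 0     otherwise (including unaligned positions)

and F_i is the mean of sco_n(i) over the N homologs, so F_i in [0, 1].
Homologs whose global TM-score to the target falls below the retention
threshold lambda = 0.3 are removed before the profile is computed; below
that score a hit is more noise than family signal, while a much higher
threshold would keep only near-copies that carry no folding information.
Unaligned target positions count as 0 for that homolog — absence of a
residue at the aligned position is itself evidence of non-conservation —
which keeps F normalized by N.

Deviations are measured at CA atoms under the TM-optimal superposition:
the inlier weighting anchors the frame on the conserved core, which is the
quantity the F statistic is meant to capture. A plain all-atom Kabsch
frame would let a large variable region drag the superposition and blur
the conserved/variable contrast.

## Restraint (statistical) potential

Target CA–CA distances d_ij are read from the input 3D model of the
target (in production use, a predicted model; in the fixtures, the
synthetic native). The restraint energy of a conformation with distances
d̄_ij is

    E_stat = sum_{i<j, |i-j| >= s} c_ij * |d_ij - d̄_ij| / d*_ij,
    d*_ij  = ln(eps + |i - j|),
    c_ij   = w_ij = 2 F_i F_j / (F_i + F_j)   (nucleation stage)
           = 1                                 (finalization stage)

The harmonic-mean weight w_ij is high only when both residues are
conserved, so conserved-core contacts dominate the nucleation stage; in
finalization the weights are dropped so low-F regions are pulled in too.
Choices that the functional form leaves open:

* `eps = 1e-3` and minimum sequence separation `s = 2`. With eps
  "infinitely small", 1/d* diverges at |i-j| = 1; adjacent-residue
  distances are fixed by covalent geometry and carry no folding signal, so
  they are excluded and eps merely keeps the logarithm finite. Both are
  configurable.
* natural logarithm; any other base is a global rescaling absorbed by the
  stage weights.
* the sum runs over unordered pairs i < j once; a doubled (ordered) sum
  would scale all statistical energies by 2, which the Metropolis
  temperature absorbs.

## Fragment library

Homologs are ranked by TM-score and the top M = floor(N * min_i F_i) are
removed: near-copies of the target would only teach the sampler the
answer, not the pathway. From each remaining candidate, every maximal
alignment block that is contiguous in both target and homolog numbering is
cut into all 6-residue and all 3-residue windows, stored in torsion space
(phi, psi, omega) and keyed by target start position; blocks of length
3–5 contribute only 3-mers. Fixed-size windows (rather than variable-length
fragments trimmed at insertion) keep positional assembly simple; the
"at least 3 / at least 6" reading applies to the blocks. Per-position
lists are deduplicated at 0.01 degrees to bound memory. When the MSTA is
uniformly identical to the target, M = N would empty the library; the
pipeline then falls back to using all homologs, which reduces the library
to the target's own torsions — the correct degenerate limit.

## Physical potential

The chain is reduced to backbone (N, CA, C, O) plus a pseudo-CB placed by
the ideal tetrahedral construction (for every residue — no per-amino-acid
centroid offsets). Two stage-specific combinations are used:

* stage 1: `E = w_vdw E_vdw + w_hb E_hb_srbb` — steric repulsion
  (((r^2-d^2)/r^2)^2 below the repulsion-radius sum, residue separation
  >= 2) plus a short-range backbone hydrogen-bond well (separations 3–5,
  distance well centered 2.9 A and zero beyond 3.5 A, times a squared
  C=O···N collinearity factor). Enough to let helices and local hairpins
  form quickly.
* stage 2 adds six centroid-level terms: pair (salt bridges -1,
  like-charge +0.5, disulfide -2 at CB contact range), env (hydropathy ×
  relative CB neighbor excess), cbeta (saturating neighbor-count
  compaction reward), sheet (-1 per strand pair with >= 2 cross-strand CA
  contacts at 4.2–5.5 A), hs_pair (-0.5 per helix/strand midpoint pair
  under 10 A) and rsigma (a 4.8 A inter-strand distance well discounted by
  register spread).

These are simple analytic forms written for this package, chosen to
reproduce each term's documented qualitative role; they are not ports of
any table-driven knowledge-based potential. All default weights are 1.0
except w_vdw = 2.0 (hard clashes must dominate every other signal); the
defaults are package choices, overridable via a TOML file. Every term
depends only on internal distances and angles and is rigid-motion
invariant to machine precision.

## Sampling protocol

Moves are fragment insertions: a window of backbone torsions is
overwritten by a library fragment and the chain rebuilt by sequential
NeRF placement with fixed ideal bond lengths/angles (N–CA 1.458, CA–C
1.525, C–N 1.329 A; angles 111.2/116.2/121.7 deg), so covalent geometry is
bit-identical in every conformation. Insertion positions are uniform over
library coverage.

1. **Initialization** — from the fully extended chain (phi -139, psi 135,
   omega 180), exactly 20·L trial 3-mer insertions scored by the stage-1
   potential, Metropolis at kT_physi = 5.
2. **Folding nucleation** — 6-mer moves for the first half of the
   iterations, then 3-mers. A trial must pass the Metropolis test for the
   weighted restraint energy at kT_stati = 2 AND for the stage-2 physical
   energy at kT_physi = 5. The AND combination means restraint
   satisfaction cannot be bought with physically unreasonable structures;
   the higher physical temperature reflects that physical energy need not
   decrease monotonically during folding, it only gates plausibility.
3. **Finalization** — same move schedule; the unweighted restraint test
   runs first and, on rejection, the physical test gives a second chance
   (OR). The weaker acceptance rule raises the acceptance rate and speeds
   convergence of the low-F regions toward the final state.

Both temperatures are constant by default (the protocol's two printed
values); an optional geometric cooling factor exists but is off (1.0).
Iteration counts default to 50·L (nucleation) and 30·L (finalization) —
package defaults sized so toy chains (L 30–80) converge in minutes on one
CPU. A single seeded NumPy generator drives every stochastic choice;
`metropolis_accept` always consumes exactly one uniform draw so replayed
streams stay aligned, and the manifest (seed + full config) reproduces a
trajectory byte-exactly.

Single-chain Monte Carlo is used throughout; the stage description in
terms of "generations" is interpreted as iterations of one chain, not a
population.

## Trajectory analysis

Nucleation-stage snapshots are clustered by greedy leader clustering on
pairwise CA-RMSD (cutoff 3 A): the first snapshot seeds cluster 1, each
subsequent snapshot joins the first leader within the cutoff or seeds a
new cluster; representatives minimize summed RMSD to co-members; clusters
are reported largest first. The leading intermediate is scored against
the native with CA-only lDDT (inclusion radius 15 A, sequence separation
>= 2, thresholds 0.5/1/2/4 A), restricted to pairs with at least one
endpoint in the region of interest. The folding order is called
consistent when

    lDDT(EFR) - lDDT(LFR) >= 0.10

an absolute difference in lDDT units (the "10 % higher" convention used
with such scores), boundary inclusive. The ensemble overlap profile
(RMSD_norm) is the min–max-normalized per-residue mean pairwise CA
deviation over the ensemble, computed from pairwise superpositions so it
is member-order invariant; it is a stand-in definition for ensemble
coloring, labelled as such. Stage statistics report helix/sheet fractions
(dihedral-basin + hydrogen-bond-pattern assignment), buried fractions
(RSA < 0.25) and the Rg series.

Relative solvent accessibility is a sphere-dot (Shrake–Rupley-style)
method over the reduced atom set (backbone + CB; 92 dots/atom, probe
1.4 A) divided by residue-specific theoretical maximum accessibilities
(Tien-style values). With side chains absent the absolute values are
generous, but the buried/exposed contrast that the statistics use is
preserved; this is explicitly an approximation to all-atom DSSP
accessibility.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes: a
family whose conserved regions deviate little from the target and whose
variable regions deviate much. Natives are built from secondary-structure
blueprints (canonical helix -57/-47, strand -139/135, coil sampled from
coil basins, clash-checked with resampling). Homologs are made by torsion
perturbation — never raw coordinate jitter — so every homolog is a valid
chain with intact covalent geometry:

1. a fixed per-homolog Gaussian noise pattern over (phi, psi) is drawn;
2. a per-region amplitude is fitted (multiplicative iteration) so the
   region's *internal* distortion — mean CA deviation after superposing
   the region onto its native counterpart — matches the chi-distribution
   expectation E|N3(0, sigma^2 I)| = 1.596·sigma of the requested
   Cartesian sigma;
3. torsion noise inside a region also swings everything downstream as a
   rigid lever; that rigid component is cancelled by optimizing the
   phi/psi of the region's first three residues (Nelder–Mead) to minimize
   the region's deviation in the conserved-core-anchored frame.

The fit makes the measured deviation a deterministic, monotone function of
the amplitude, which an open-loop noise scale cannot achieve (chain-level
deviations under torsion noise are heavy-tailed). Default study
conditions for the two-region benchmark: sigma 0.5 A (conserved) vs 3.0 A
(variable), 20 homologs, 2 random-torsion decoys (which the TM >= 0.3
filter removes), L = 40, EFR = the conserved half. Random decoys and
identity hit rows are emitted in the exact formats the pipeline consumes
(PDB, Foldseek-style TSV, annotation TSV).

What the generator does *not* emulate: real evolutionary divergence
(insertions/deletions beyond alignment gaps, correlated domain motions),
predicted-model error profiles, or sequence divergence (homologs keep the
target sequence). Passing the recovery tests therefore shows the pipeline
extracts and uses region-wise structural conservation correctly — not
that it matches any particular experimental system.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline on L = 40 chains with 20
homologs and 10 seeds — large enough for a clear conserved/variable
contrast, small enough for minutes-scale runs. TM-score search uses
multi-seed iterative inlier refinement plus d0-weighted polishing and is
validated against a numeric superposition-search oracle to 0.01; lDDT is
validated against brute-force enumeration to 1e-9. Ties in the
redundancy cut are broken by input order (stable sort). Degenerate cases:
an all-identical ensemble yields F = 1 everywhere and the native-torsion
library (see above); an ensemble overlap profile with zero spread is
defined as all-zero; chains shorter than 3 residues are rejected by the
alignment and superposition layers.

## Known limitations

* Centroid-level physics with hand-written analytic terms: adequate to
  rank toy decoys and drive compaction, not calibrated against any
  experimental energy scale.
* The final-state TM-score depends strongly on fragment quality; with
  noisy-family fragments the final state is typically TM 0.4–0.5 on the
  toy fixture, reaching ~1.0 only in the identical-homolog limit.
* CA-only lDDT and backbone+CB accessibility are proxies for their
  all-atom counterparts.
* Single trajectory per run; no replica exchange or population dynamics.
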