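# Methods

## Structure model and normalisation

Coordinate files (PDB and mmCIF, read through gemmi) are normalised into
a chain/residue/atom model addressed by **author numbering** — chain id,
residue number, insertion code — because that is how active-site residues
are referred to in practice (F153, H250, …). Normalisation rules:

- Alternate locations collapse to the highest-occupancy conformer; ties
  break to the alphabetically first altloc letter, so parsing is
  deterministic.
- Hydrogens are removed: crystal structures in the 1.7–1.9 Å range carry
  no reliably placed hydrogens, and every measure here is heavy-atom
  based.
- Waters and other hetero residues are retained as ligands, outside the
  polymer; selenomethionine (MSE) is treated as methionine and stays in
  the polymer.
- Sequences extracted from a chain span the full author-number range with
  gap characters at missing numbers, so disordered stretches are visible.

## Superposition

`kabsch_fit` solves the orthogonal Procrustes problem by SVD with the
determinant correction that forbids reflections. `align_reject` is the
iterative variant common to structure-comparison tools: refit after
discarding pairs whose residual exceeds `reject_factor` (default 2.0)
times the current RMSD, up to `max_cycles` (default 5) or until stable.
The schedule is a stated convention, not a fact about any particular
published comparison, and both knobs are arguments. A floor of 10⁻³ Å on
the rejection cutoff keeps numerically perfect fits from discarding pairs
on rounding noise. Degenerate input (fewer than 3 pairs, collinear
reference points) is an error rather than a silent bad fit.

The test suite and acceptance script check the SVD route against an
independent quaternion (Horn) eigenvalue implementation; the two agree to
better than 10⁻⁶ Å RMSD on random instances.

## Domain motion

Open/closed comparisons are made in the **anchor frame**: the mobile
model is rigidly superposed on the reference by the designated rigid
domain (for a COMT-type protomer, the dimerization domain), and every
downstream quantity is measured in that frame.

- The moving domain's residual transform (Kabsch fit of its matched Cα)
  is decomposed as a screw motion: angle from θ = arccos((tr R − 1)/2)
  with the argument clamped to [−1, 1]; axis from the antisymmetric part
  of R (eigen-decomposition fallback near 180°); translation split into a
  shift along the axis and an in-plane part absorbed by the anchor point
  solving (I − R)p = t⊥ in least squares. Angles below 0.1° report an
  undefined axis rather than amplified noise.
- Displacement fields are per-residue Cα vectors (mobile − reference)
  with mean/RMS/max statistics. Field differences (for asking whether two
  transitions are the *same* motion) are taken over the residue
  intersection.
- Backbone φ/ψ use the standard four-point torsion; chains split into
  segments at numbering gaps or Cα–Cα distances above 4.5 Å (beyond any
  plausible peptide bond), and dihedrals never span a break. Kink deltas
  are circular (178° vs −178° differ by 4°).

Default COMT-type domain boundaries (dimerization 5–131, interdomain
helix 150–170, Rossmann-like 171–340, author numbering) are configurable
defaults chosen from the family's secondary-structure layout, not
measured facts; users analysing a specific deposition should supply their
own.

## Surface area and interfaces

SASA is Shrake–Rupley: each atom's van der Waals sphere (C 1.70, N 1.55,
O 1.52, S 1.80 Å, fallback 1.70) inflated by the probe radius (default
1.4 Å) is sampled with a 960-point Fibonacci lattice; the accessible area
is the unburied fraction times the inflated sphere's area. Doubling the
point count moves totals by well under 1 % on convex fixtures. Interface
area is the standard half-difference (SASA_A + SASA_B − SASA_AB)/2,
clamped at zero; it is symmetric by construction and zero for
well-separated groups. A cross-check against biotite's independent
Shrake–Rupley implementation is part of the test suite.

## Grid-probe cavity detection

The cavity detector follows the grid-probe (POCASA-style) scheme with the
conventional parameters: 0.5 Å grid, 3 Å probe, count trim 11 points,
depth trim 10 grid steps.

1. A cubic grid covers the atom bounding box padded by probe + max vdW.
2. Points inside any atom's vdW sphere are PROTEIN.
3. Probe centers are points outside the probe-inflated protein **that are
   connected to the box boundary** — the probe rolls in from bulk, so a
   probe-sized void sealed inside the protein is a cavity, not solvent.
   Every empty point within one probe radius of a reachable center is
   SOLVENT.
4. Remaining empty points are pocket candidates, grouped by
   6-connectivity (conservative; no diagonal leakage at 0.5 Å).
5. Groups smaller than the count trim, or whose maximum burial depth
   (taxicab grid steps to the nearest solvent point) is below the depth
   trim, are discarded. The depth trim is expressed in grid steps and so
   scales with the grid spacing.

Ligands and waters are excluded before cavity computation so that
liganded and unliganded conformers are comparable. Absolute grid-probe
volumes depend on each tool's trimming semantics; the open/closed
**ratio** (`cavity_reduction`) is therefore the primary statistic. On the
analytic benchmark — a watertight atom shell enclosing a 6 Å spherical
cavity — the detector recovers 904.8 ų to about 1 % at the default grid;
the residual error at fine grids is dominated by the physical crevice
volume between shell atoms, not discretization.

## Contacts

All criteria are heavy-atom distances with chemical typing: hydrogen
bonds are donor–acceptor pairs (backbone N/O, typed side-chain atoms,
waters as both, ligand N/O by element) within 3.5 Å; an optional
antecedent-angle filter (≥ 90°) exists but is off by default because
distance-level statements are the norm for no-hydrogen crystal models.
Salt bridges pair Arg/Lys/His charged-group nitrogens (plus N-termini)
with Asp/Glu carboxylate oxygens (plus C-termini) within 4.0 Å. The
default contact cutoff is 4.0 Å. Contact lists are canonically oriented,
so selection order never changes the result, and enlarging a cutoff never
removes a record.

## Motif tiers and sequence networks

Reference positions are mapped onto target sequences by BLOSUM62 global
alignment (gap open 10, extend 0.5); a position falling in a deletion is
"gapped" and fails every pattern. The stringency tiers are nested pattern
pairs over positions 153/157 and 297/301:

| tier | slot 1 | slot 2 |
|---|---|---|
| yellow | FxxxM | MxxxM |
| orange | FxxxM | [FYML]xxxM |
| maroon | [FL]xxx[ML] | [FYML]xxx[FML] |
| purple | [FL]xxx[ML] | xxxx[FML] |

A sequence is assigned the most stringent tier both of whose slots match;
nesting (yellow ⊆ orange ⊆ maroon ⊆ purple) holds by set inclusion and is
property-tested against an independent regex oracle. Cluster fractions
are reported cumulatively by default (a yellow sequence counts toward all
four tiers), with an exclusive mode available.

The SSN edge weight is AS = (λS − ln(K·m·n))/ln 10, a −log₁₀ E-value
transform of the BLOSUM62 Smith–Waterman score with ungapped
Karlin–Altschul constants λ = 0.267, K = 0.041. Database-scale E-values
from network services are not reproducible offline; this score is a
documented stand-in with the same ordering behaviour, all thresholds are
arguments, and absolute cluster membership of any external database
network is explicitly not a target. Clusters are connected components at
the threshold; raising the threshold only ever refines them.

## Synthetic generators

All generators are pure functions of (spec, seed).

- **Conformer pairs**: poly-alanine backbones from ideal peptide geometry
  (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; ideal angles; ω = 180°) with
  helical φ = −57°, ψ = −47°, verified to round-trip through the dihedral
  module to 0.01°. Domain B of the closed copy is rotated by the
  specified hinge; optional Gaussian noise (per coordinate, independent
  per copy) is added after the truth record — exact displacements and
  per-residue axis distances — is captured. Poly-alanine suffices because
  every implemented measure except side-chain contacts is backbone/Cα
  based; contact toys place explicit pseudo-atoms instead.
- **Cavity shells**: Fibonacci-lattice atom shells (near-uniform coverage,
  one density parameter) with analytic enclosed volume
  (4/3)π(R − r_vdW)³; an aperture cone (full apex angle) can open the
  cavity, and the analytic truth reports 0 when the hole admits the
  probe. A leak check warns when the lattice spacing cannot be
  watertight.
- **Motif families**: a fixed 340-residue scaffold (or caller-supplied
  unrelated scaffolds for multi-family sets) mutated at a per-site rate,
  with tier and catalytic residues planted after mutation so the truth
  labels are exact. Tier fractions are cumulative and must respect
  nesting.

What the generators do **not** emulate: realistic packing, side-chain
rotamers, B-factors, crystal contacts, or homologous-family substitution
structure. Passing the recovery tests shows the estimators are correct on
their stated geometric/sequence models, not that any particular crystal
pair will be noise-free.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately small instances:
25–80-residue domains, 100-replicate noise grids, ≤ 12-point oracle
instances, 18-sequence networks, ~60³-point cavity grids — sizes at which
every stage completes in seconds while still exercising the full code
path. Hinge-recovery tolerances are simulation-derived: the error scale
is the RMS recovery error across replicates (absorbing the small-angle
bias of a non-negative angle estimator), with the within-3σ fraction held
to the distribution-free Chebyshev floor because a rod-like domain's
rotation about its own axis is weakly constrained, making the error
distribution heavy-tailed. The cavity-volume tolerance (10 %) reflects
0.5 Å discretization of a ~6 Å feature; the SASA tolerance (1 %) reflects
960-point sampling.

## Limitations

- No automated domain decomposition: domain boundaries are user input.
- No sequence-independent (fold-matching) structural alignment.
- Hydrogen bonds are distance-plus-typing only; no orbital geometry.
- Grid-probe volumes are comparable within this implementation, not
  across tools with different trimming semantics.
- The SSN score reproduces orderings, not database E-values; "monomer
  length" style global measures and cross-structure water matching are
  out of scope.
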