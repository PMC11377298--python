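# Methods

This note records the models, defaults and numerical choices behind
helixweaver, and what the synthetic test data does and does not probe.

## Backbone model

Chains are all-α backbones: atoms N, CA, C, O per residue (CB optional,
placed at the ideal tetrahedral position from N, CA, C).  Construction is
purely internal-coordinate: given per-residue torsions (φ, ψ, ω in
degrees, with φ undefined at the first residue and ψ/ω at the last), atoms
are placed sequentially (NeRF-style) with fixed bond lengths and angles:

| quantity | value |
|---|---|
| N–CA, CA–C, C–N, C=O | 1.458, 1.525, 1.329, 1.231 Å |
| N–CA–C, CA–C–N, C–N–CA, CA–C–O | 111.2°, 116.2°, 121.7°, 120.8° |

These are standard Engh–Huber-style values.  The carbonyl O lies in the
carbonyl plane anti to the next amide N (dihedral ψ + 180°); at the C
terminus, where ψ is undefined, a helical pseudo-ψ of −45° keeps the
placement deterministic.  Consequently, when a chain is grown C-terminally
the junction residue's O is re-derived once its ψ becomes defined; all
other existing coordinates are bitwise unchanged.  N-terminal growth
rebuilds the chain from the concatenated torsion sequence and re-indexes.

Construction and measurement are exact inverses: re-measuring torsions
from built coordinates reproduces the inputs to ≪ 1e−6°, which the test
suite verifies both internally and against mdtraj's dihedral routines.
The canonical α-helix torsions (−60, −45, 180)° give a rise of ≈ 1.54 Å
per residue and ≈ 3.63 residues per turn.

ABEGO torsion bins (the bin boundaries are the de-facto convention;
|ω| < 90° is cis): φ < 0 → 'A' if −75 < ψ ≤ 50 else 'B';
φ ≥ 0 → 'G' if −100 < ψ ≤ 100 else 'E'; cis → 'O'.

## Helix assignment

Rather than shelling out to a DSSP binary, the package implements the
published criterion directly: an ideal amide H is placed 1 Å from N along
the bisector of the C(i−1)→N and CA→N directions, the Kabsch–Sander
electrostatic energy 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol is evaluated for all candidate CO(i)→NH(j) pairs, and a hydrogen
bond exists below −0.5 kcal/mol.  Two consecutive i→i+4 turns make
residues i..i+3 helical; only maximal runs of ≥ 5 'H' residues are
reported as α-helices, everything else is loop.  mdtraj's DSSP serves as
an independent cross-check in the tests (agreement is asserted on helix
cores; boundary residues may differ by one because of H-placement
details).  Note that 5-residue helices produced by the enumeration lower
bound have interior 'H' runs shorter than 5 and are therefore *not*
re-assigned as helices when a generated structure is re-scored — scored
helix counts can be lower than generative helix counts, which mirrors how
assignment-based and blueprint-based helix definitions differ in practice.

## Helix axes and HLH featurization

A helix axis is the first principal component of the span's centered CA
coordinates, sign-oriented N→C.  PCA is a pragmatic estimator that is
robust down to the 5-residue minimum span; note its axis tilts by a few
degrees on spans covering a fractional number of turns, which is why the
bundle fixture aligns on interior spans.

Each HLH unit (two helices ≥ 5 residues, loop of 1–5 residues) is
summarized by five rigid-motion-invariant numbers:

1. bend *b* = 180° − ∠(u₁, u₂) (degrees; 0 = antiparallel hairpin);
2. the dihedral of the two axis segments (endpoints = axis projections of
   each helix's terminal CAs), capturing handedness (degrees);
3. the junction CA–CA distance (Å);
4. ∠(u₁, m₂−m₁) and 5. ∠(u₂, m₂−m₁), the packing angles between each
   axis and the midpoint-joining vector (degrees).

This particular five-vector is the package's own concrete choice for "a
five-feature HLH geometry": it spans bend, chirality, junction scale and
mutual packing, and is explicit configuration rather than a claim that no
other parameterization would serve.  Bend-class thresholds default to
h < 50° ≤ v < 85° ≤ c and are configurable.

## Density-peak clustering

Implemented from the algorithm's definitions: Gaussian-kernel density
ρ_i = Σ_{j≠i} exp(−(d_ij/d_c)²); separation δ_i = distance to the nearest
higher-density point (global maximum: largest pairwise distance); centers
are the top-(ρ·δ) points (or a requested count); remaining points follow
their nearest higher-density neighbour in decreasing-density order.
Features are z-scored per component before distances; d_c defaults to the
2nd percentile of pairwise distances.  All ties (equal ρ, equal ρ·δ) break
by point index, making the partition permutation-stable.  The class
follows the scikit-learn estimator contract (`fit`, `fit_predict`,
`labels_`, `get_params`) so it composes with sklearn tooling.

Motif budgets across loop lengths 1–5 (18 total by default) are
apportioned proportionally to the number of units per length
(largest-remainder), overridable per length.  Each cluster's
representative is its density-peak member; its loop torsions plus the
junction pseudo-torsions (ψ/ω of the preceding helix residue, φ of the
following one) populate the motif record, whose stored bend angle is
measured on the rebuilt ideal-helix–loop–ideal-helix chain so record and
rebuild agree by construction (within 2° is asserted).

## Clash and compactness filters

The steric filter is a documented soft-sphere score, not a re-derivation
of any particular force field: weight × Σ max(0, σ_ij − d_ij)² over atom
pairs at least two residues apart, with per-element radii N 1.55, C/CA/CB
1.70, O 1.52 Å.  Contact distances for N–O pairs are scaled by 0.95 so
that backbone hydrogen bonds (O…N ≈ 3.0 Å in an α-helix) are not counted
as overlap; without this a single ideal helix would score slightly
positive.  Defaults: weight 0.1, accept while the weighted score is
< 4.0, applied to every partial chain during growth (required for
tractability and consistent with staged clash-free intermediates).
Compactness is the unweighted RMS CA distance from the CA centroid,
accepted below 14 Å.  Both thresholds are configuration.

## Staged enumeration and its counting oracles

Backbones grow one (motif, helix) block per stage; stage budgets pin the
cumulative residue count after selected stages.  The default schedule
mirrors the full-scale pipeline: five helices at 90 residues grow through
a 70-residue four-helix intermediate; six helices at 110 residues extend
the five-helix set N-terminally.  When a budget leaves exactly one
admissible helix length per motif, each parent yields exactly
library-size children — the forced-extension rule.  Counters report the
full-length children tested (pre-clash), those passing the clash filter,
and those additionally passing Rg, so both "counted before" and "counted
after" the final clash evaluation are available.

Two analytic oracles guard the engine: a dynamic-programming count of
bounded helix-length compositions (exact match with brute force and with
filter-disabled engine runs on a randomized suite), and the
forced-extension product rule (asserted against live engine counters).
Desk-scale runs in the tests and examples use 2–3 helices and 24–36 total
residues with toy libraries of 1–18 motifs — sizes chosen so the whole
suite exercises every code path in seconds; the full-scale billions-scale
enumeration is out of scope for a single workstation and is represented
by the counter arithmetic instead.

Output entries are sorted lexicographically by motif-id sequence then
helix lengths, and a materialization cap bounds memory while counters
remain exact.

## Helix order

HO = 2/(N(N−1)) Σ_{i<j} (u_i·u_j)² over N ≥ 2 unit axis vectors.  It is
invariant to axis sign flips and relabeling, bounded in [0, 1] by
Cauchy–Schwarz, equals cos²θ for a pair at angle θ, and has isotropic
expectation 1/3 (E[(u·v)²] = 1/3), all asserted in the tests.  Structures
with fewer than two assignable helices report HO as undefined (None)
rather than 0, so distribution summaries are not polluted.  Selection
modes: `lowest_ho` (k smallest, ties by lexicographic topology identity)
and `motif_coverage` (greedy maximal new-motif coverage, ties by lower
HO).

## Synthetic data: what it emulates and what it does not

The fixtures module generates every input the pipeline needs from a seed:

- **Oriented bundles** place rigid ideal helices with prescribed axis
  directions in a daisy-chain layout joined by interpolated (geometric,
  non-torsional) linker residues, retrying lateral offsets until the
  rigid placement is clash-acceptable.  They give exact control over HO
  for scoring tests.
- **Toy motif libraries** rejection-sample loop torsions from ABEGO-bin
  distributions until each bend class holds the requested count; every
  record rebuilds clash-acceptably between ideal helices.
- **Feature mixtures** are isotropic Gaussian blobs with retained labels
  for planted-truth clustering checks.
- **Toy PDB sets** are torsion-built multi-helix chains with non-helical
  loops of 1–5 residues, guaranteed to contain minable HLH units.

None of these reproduce the conformational diversity, loop-torsion
statistics or packing of native structures, so green tests demonstrate
algorithmic correctness (recovery of planted structure, exact counts,
closed forms), not that a mined library from real coordinates would match
any published motif set.  Mining a real library additionally requires a
curated non-redundant structure set, which users supply themselves.

## Known limitations

- The soft-sphere clash score is not numerically interchangeable with any
  force-field repulsion term; only its thresholds are shared convention.
- PCA axes on short or bent helices are estimates; bend angles inherit a
  few degrees of estimator noise.
- The helix assigner implements only the α-helix ('H') pattern of the
  hydrogen-bond formalism; strands and 3₁₀/π helices are reported as loop.
- Enumeration cost grows as (library size × helix-length range)^stages;
  full-scale runs need sharding (e.g. by first motif), which is left to
  the caller.
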