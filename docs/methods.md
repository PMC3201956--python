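# Methods

This note documents the models, numerical choices and limitations behind
`allosite`, in the order the pipeline runs them.

## Conformer ensemble and superposition

Equivalent residues across conformers are matched by identical
`(chain, resid, icode)` keys, or by an explicit user-supplied equivalence
table when author numbering differs between structures (e.g. across Ras
isoforms). No automatic sequence alignment is attempted: the tool targets
families where the numbering is conserved or curated, and a wrong silent
alignment would corrupt every downstream stage.

Superposition is a Kabsch least-squares fit (SVD of the 3×3 cross-covariance,
determinant-corrected to a proper rotation). Ensembles are aligned by a
progressive-mean scheme: fit everything to the first conformer, then twice
to the running mean; RMSD is reported over the fit indices. Degenerate fits
(< 3 points, collinear geometry) raise rather than returning an arbitrary
rotation.

**Invariant core.** The superposition frame is found iteratively: superpose
on the current candidate set, score each position by the volume of its
positional covariance ellipsoid, (4/3)π·√(λ₁λ₂λ₃) over the 3×3 per-position
covariance (divisor N−1), and drop the worst position until all remaining
volumes are ≤ 0.5 Å³ (default) or 30% of positions remain. The ellipsoid
volume is a three-dimensional scatter measure: positions moving strictly
along a line or arc score near zero and stay in the core, which is the
intended behaviour — a 1-D hinge motion does not destabilise a least-squares
frame the way isotropic disorder does. A floor of 3 surviving positions is
enforced (fit feasibility).

## Cα PCA, clustering, representatives

PCA diagonalises the full 3N×3N covariance of equivalent-Cα coordinates
(divisor N−1; eigendecomposition is cheap because the number of conformers
and residues is small in this setting). Eigenvector signs are fixed by the
convention that the largest-magnitude component is positive, making
projections reproducible across platforms. Invariants enforced by tests:
eigenvalue sum equals the covariance trace (≤ 1e-6 relative), columns
orthonormal (≤ 1e-8), mean projects to zero.

Conformers are clustered by average linkage (UPGMA, scipy) on either
Euclidean distances in PC1–3 space or a pairwise-RMSD matrix — both modes
are exposed because they give similar major groupings on real ensembles and
the choice is a user decision. The tree is cut at an explicit k (defaults 7
for crystal-style, 8 for MD-style ensembles) rather than by dendrogram
inspection; cluster labels are renumbered by descending population with
lowest-member-index tie-breaks, so outputs are deterministic given input
order. The representative of each cluster is the member with the lowest
plain RMSD to the cluster-average coordinates (coordinates are already in
a common frame; ties go to the lowest conformer index).

χ1 side-chain dihedrals (N–CA–CB–CG, IUPAC sign, range (−180°, 180°]) are
computed per conformer with missing-atom conformers contributing NaN plus a
warning; the density is a normalised histogram with 10° bins by default.
The sign convention was cross-checked against MDAnalysis on random
geometries.

## Probe occupancy and pocket definition

A residue is in contact with a probe pose when any heavy-atom pair is
strictly within 5.0 Å (hydrogens never participate; strict `<` at the
cutoff). Raw occupancy counts accumulate over all (conformer, pose) pairs
— this granularity is retained so coarser conventions (per conformer, per
probe cluster) can be recovered. Normalisation divides by the ensemble-wide
maximum count, giving values in [0, 1] with the maximum attained; an
alternative mode divides by n_conformers × n_poses for an absolute
frequency reading.

Hot residues (occupancy ≥ floor, default 0.25) become pockets by
single-linkage clustering of their Cα positions at 8 Å: single linkage is
the right topology for surface patches, which are elongated rather than
globular. Pockets are labelled p1, p2, … by descending mean occupancy;
residues in a caller-supplied nucleotide-contact set are segregated into an
"active-site" pocket (`nuc`) so that catalytic-site signal does not absorb
the allosteric sites.

## Affinity grid and envelope search

The grid stage needs only *an* energy landscape with realistic shape, not a
force field: each point carries a single-probe Lennard-Jones sum
Σ 4ε[(σ/d)¹²−(σ/d)⁶] with ε = 0.2, σ = 3.4 Å (a generic carbon-like probe),
distances clamped at 0.5 Å, and points within 2.0 Å of any heavy atom
excluded as clashes (+∞). Grid spacing defaults to 0.375 Å with a 4 Å
bounding-box pad.

The binding-envelope search looks for the contiguous set of n = 70
favourable points (70 prospective ligand-atom centres ≈ a drug-sized
volume). Finding the optimal connected fixed-size subset is NP-hard in
general, so the search is greedy with restarts: grow from each of the 10
lowest-energy seeds by repeatedly absorbing the cheapest 26-connected
neighbour, keep the envelope with the lowest total energy, break ties by
grid index. Optimality is not guaranteed; the property tests verify
exactness against exhaustive enumeration on every random 3×3×3 instance
tried, and the multi-seed restart bounds the damage of a bad seed on larger
grids.

## Pocket volumetry

Volume is measured per conformer after core superposition: lattice points
(spacing 1.0 Å default) inside an inclusion sphere at the pocket-residue Cα
centroid (radius 8 Å default; the sphere is the user region a practitioner
would draw), minus points within (Bondi vdW radius + 1.09 Å) of any protein
heavy atom, keeping only the largest 26-connected component so detached
crevices do not inflate the number. Volume = count × spacing³; mean and SD
(divisor N−1) over conformers. The exclusion pad 1.09 Å is a hydrogen-ish
probe radius. Exact behaviour is pinned by lattice-count oracles (the empty
r = 5 Å sphere at spacing 1.0 contains exactly 515 lattice points) and by
convergence to 4/3·π·r³ as spacing shrinks. Unknown elements fall back to a
1.7 Å radius with a warning.

## Blind-dock aggregation

Pose→pocket assignment maximises |contact residues ∩ pocket residues| /
|contact residues| and requires at least 0.3 overlap (both parameters
exposed; the underlying aggregation literature states no rule, so the rule
had to be a design choice here). Site preference weights each compound
equally by its per-site pose frequency, then averages over compounds —
weights always sum to 1 and are invariant to pose/compound order.

Hydrogen bonds use donor–acceptor < 3.5 Å (strict) and D–H···A angle in
[150°, 180°] (inclusive, matching the "less than" / "between" semantics of
the defining cutoffs); both ligand→protein and protein→ligand directions
are scanned, protein donors being N/O atoms with a hydrogen within 1.25 Å.
Donor/acceptor typing for ligands is explicit in the pose object (docking
outputs carry polar hydrogens); for the protein an N/O heuristic is used.
Van der Waals contacts are carbon–carbon pairs < 5.0 Å.

Hit ranking: a compound must target one modal site in ≥ 50% of its poses
(threshold exposed — "consistent binding" is not quantified anywhere
authoritative), must not target an excluded (nucleotide) site, and must
pass the Lipinski filter; survivors are sorted ascending by best (lowest)
predicted Ki with compound-id tie-breaks.

## Consensus screening and Lipinski

Score tables must declare per-function orientation because absolute scores
of different scoring functions are not comparable; only ranks are merged.
Top-k (default 20) lists per function are unioned with provenance; overlap
between crystallographic- and MD-ensemble hit sets requires same-site
agreement for the "shared" class. Tanimoto similarity is plain set algebra
|A∩B|/|A∪B| on caller-supplied fingerprint bit sets (fingerprint generation
is deliberately out of scope; both-empty is defined as 0).

Lipinski descriptors: nON counts N and O atoms, nOHNH counts hydrogens
bonded to N or O (explicit-H molecular graph required), MW sums standard
atomic weights (gemmi's element table), logP is passed through from input —
no in-house logP model. The filter is inclusive at the bounds (MW = 500
passes). Two strictness modes exist because published hit lists routinely
retain one-violation compounds: `classic` (≤ 1 violation, default) and
`strict` (0 violations). The bundled 19-compound reference descriptor table
passes entirely under `classic` while exactly its three >5-donor compounds
fail under `strict`, which is the behaviour the tests pin.

## Synthetic fixtures

Generators are pure functions of (parameters, seed), RNG =
`numpy.random.default_rng`. The toy ensemble lays Cα atoms on an idealised
helix (3.6 residues/turn, self-avoiding), adds planted collective modes
with per-conformer amplitudes plus isotropic Gaussian noise, and regenerates
(≤ 100 attempts) if atoms land within 1.0 Å. Probe poses place a configured
fraction within 4 Å of planted pocket centroids, the rest on a surface
shell; dock poses draw sites from a per-compound multinomial preference row
with log-uniform Ki; score tables share a latent ranking to degree ρ with
orientation randomised and declared.

What the fixtures do *not* emulate: real protein stereochemistry (only Cα
traces), solvent and crystal-contact artefacts, correlated (non-isotropic)
noise, realistic probe chemistry, or score distributions of actual scoring
functions. Passing the recovery tests therefore demonstrates the
correctness of the aggregation/statistics machinery under the assumed
generative structure, not performance on experimental data.

## Problem sizes and defaults

The default test and acceptance runs use deliberately small instances —
10–50 residue toy ensembles, 4–15 conformers, 3×3×3 grids for exhaustive
envelope oracles, 50–100 seeded trials per recovery statistic — chosen so
the oracles (exhaustive enumeration, O(n²) brute force) remain feasible and
the full suite runs in about a minute. All geometric parameters default to
the field-standard values quoted above and every one is overridable through
the library API, the CLI flags and the pipeline config file.

## Known limitations

* Envelope search is heuristic beyond exhaustively-tested grid sizes.
* Residue equivalence across structures with different numbering requires
  an explicit table; there is no alignment fallback.
* The affinity grid's LJ stand-in ranks cavities sensibly but its energies
  are not calibrated to any physical unit.
* Protein donor detection relies on explicit hydrogens; structures without
  hydrogens contribute acceptor-side bonds only.
* Volume SD over very few conformers (N < 3) is statistically weak; N = 1
  reports SD 0.
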