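# Methods notes

This note records the models and procedures the package implements, the
numerical and design choices made where conventions differ between
tools, and what the synthetic-data generators do and do not emulate.

## Superposition and the RMSD/RMSF family

Rigid-body fitting uses the classic Kabsch construction: centroids
removed, rotation from the SVD of the cross-covariance with a
determinant sign correction so the rotation is always proper. Collinear
point sets are rejected (the rotation about the line is undetermined).
No mass weighting is applied anywhere.

RMSF is measured about the ensemble mean with a two-pass alignment:
frames are first fitted to the first kept frame, the mean structure is
computed, and frames are re-fitted to that mean. Fitting to the mean
rather than to frame 1 is the standard essential-dynamics convention and
removes the alignment bias a single arbitrary reference introduces. The
equilibration cut defaults to discarding the first half of the frames,
matching the common practice of analyzing only the converged tail of a
production run; a time-based cut (ns) can be given instead.

Sub-range RMSD (used for the activation helix, helix 12) performs a
*global* fit on the fit selection and measures only the range's Cα
atoms, so genuine local motion is not hidden by a local fit. Default
helix-12 ranges are 448–468 (α), 421–441 (β), 457–477 (γ), exposed as
configuration. Histograms use 0.5 Å bins from zero. Whether a ligand
RMSD uses a protein fit or a ligand fit is exposed as the choice of fit
selection; the protein fit is the default reading.

## Frame clustering

Frames are clustered by average-linkage agglomeration on the pairwise
fitted-RMSD matrix, merging while the minimum average inter-cluster
distance stays within the merge cutoff (default 2.5 Å). The linkage is
delegated to `scipy.cluster.hierarchy` (UPGMA) and cross-checked in the
test suite against a naive O(n³) merge loop. The centroid of a cluster
is the member with the most neighbors within the neighbor cutoff, which
defaults to the merge cutoff since nothing in the protocol separates
the two; ties (equal neighbor counts) go to the smallest frame id for
determinism. Reports retain clusters with population strictly above 1 %.
Distances are RMSD, not squared RMSD. For long trajectories a stride
subsamples frames before the O(n²) matrix; the all-pairs fitted RMSD is
evaluated with the closed-form singular-value expression batched over
pairs, which is exact and keeps 10³-frame matrices at a few seconds.

## Dynamical network model

Nodes are residues, positioned at the Cα (a ligand residue contributes
one node at its heavy-atom centroid; a named ligand atom can be chosen
instead — the centroid is the default because no single ligand atom is
canonical). Edges join residues whose heavy atoms come within 4.5 Å in
at least 75 % of frames. The 75 % occupancy is the protocol's stated
threshold; a 70 % preset is also provided since both figures circulate,
and the flag makes the choice explicit. Residue pairs within two
sequence positions on the same chain are excluded to avoid trivial
covalent contacts; a flag disables the exclusion.

Correlations are normalized displacement covariances over frames,

    C_ij = ⟨Δr_i · Δr_j⟩ / (⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩)^½ ,

computed after a global Cα alignment (two-pass, to the ensemble mean)
with temporal means removed per node. A node with zero variance has no
defined correlation and is reported as an error naming the node. For
synthetic ensembles generated directly in the fitted frame the
alignment can be skipped (`align=False`); re-fitting such data subtracts
the per-frame centroid of the noise and biases small-system
correlations downward, which matters when validating planted values.

Edge weights are w_ij = −log |C_ij| with the natural logarithm: the
weight is an information-transfer *distance*, short for strongly
correlated pairs. The base only rescales all weights, so shortest paths
and betweenness rankings are invariant to it. |C| is floored at 1e−12
(logged) to keep weights finite.

Communities come from the Girvan–Newman procedure: iteratively remove
the edge of highest betweenness, where shortest paths use w as length
with equal splitting among degenerate paths, and return the
connected-component partition of maximum modularity over the removal
sequence. Two conventions had to be fixed:

- **Tie rules.** Equal-betweenness edges are removed lexicographically
  smallest first; equal-modularity partitions resolve to the earliest
  (coarsest). Both exist purely for determinism.
- **Modularity weighting.** Modularity needs an *affinity* (coupling
  strength), not a distance. It is therefore evaluated on
  exp(−w) = |C| per edge; computing it on w itself would reward weakly
  correlated groupings. For graphs without weights every edge counts 1.

For each pair of communities joined by at least one edge, the
connecting edge of highest betweenness (on the full graph) is critical,
and its endpoints are the critical nodes — the residues mediating
inter-community communication.

Betweenness and modularity evaluation are delegated to networkx; the
removal loop, stop rule and critical-element extraction are this
package's. The test suite checks both betweenness and full partitions
against brute-force enumeration (Floyd–Warshall path counting, direct
double-sum modularity) on random weighted graphs.

## Normal modes

PCA diagonalizes the 3N×3N covariance of aligned, mean-removed node
displacements with the sample (n−1) normalization; eigenvalues are
reported in Å², descending, and the default of five modes follows the
analysis protocol. PCA is unweighted. Mode signs follow the convention
that the largest-magnitude component is positive. The per-mode RMSF of
residue i is √(λ_k |v_k,i|²); summed in quadrature over all modes it
reproduces the total fluctuation profile. Block PCA splits the
trajectory into contiguous blocks and reports absolute inner products
between corresponding modes as a stationarity check (for stationary
sampling, mode-1 overlap is near 1; for independent noise it falls to
the random-vector level ≈ 1/√(3N)).

The ANM builds the standard elastic-network Hessian — uniform springs
(γ = 1) between Cα pairs within 15 Å, the common default of public ANM
servers — and requires the contact network to be connected (the error
names the component sizes otherwise). Exactly six eigenvalues vanish
for a connected 3-D structure (five for a dimer); they are identified
relative to the largest eigenvalue (1e−8 ratio) and excluded from the
reported internal modes.

## Interaction profiling

Criteria, applied per frame between protein and ligand:

- hydrogen bond: H···acceptor ≤ 2.5 Å, donor angle D–H···A ≥ 120°, and
  acceptor angle X–A···H ≥ 90° for some heavy atom X bonded to the
  acceptor;
- hydrophobic: carbon–carbon ≤ 3.6 Å between apolar carbons, an apolar
  carbon being one with no O/N/S within 1.7 Å (distance-inferred
  bonding, perceived on the first frame);
- ionic: charged-group centroids ≤ 3.7 Å — Asp/Glu carboxylates and
  Lys/Arg amine/guanidinium groups on the protein side; on the ligand
  side carboxylates (a carbon bonded to two H-free oxygens) and
  protonated amines (N with ≥ 2 bonded H) perceived from geometry;
- water bridge: one water simultaneously hydrogen-bonded to protein and
  ligand under relaxed criteria (H···A ≤ 2.8 Å, donor angle ≥ 110°).

A protocol description phrased as contacts "within 2 Å" is not usable
as a heavy-atom criterion — 2 Å heavy-atom separations are sterically
impossible — so the thresholds above, the de-facto defaults of the
simulation-interaction-diagram style of analysis, are used instead.
Aromatic stacking is folded into the hydrophobic ring-carbon contacts
rather than classified separately. Without explicit hydrogens the
H-bond and water-bridge categories are disabled with a warning.

The interaction fraction of a (residue, category) pair is the number of
distinct frames with at least one event divided by the total frames;
the report keeps pairs at or above the 30 % threshold (inclusive). The
threshold applies per (residue, category) by default; a union-over-
categories mode is available, since either reading of "maintained an
interaction for 30 % of the time" is defensible.

Torsions use the standard atan2 dihedral on (−180°, 180°], with 10°
bins (36 per histogram, mass normalized to 1); frames with collinear
geometry are skipped and counted.

## MM-GBSA bookkeeping

The input is a long-format table of (frame, entity, term, value) with
entities {complex, receptor, ligand} and terms {coulomb, hbond,
gb_solvation, vdw, pi_pi, self_contact, lipophilic} — a neutral schema,
since the native output of end-point free-energy codes is proprietary.
Per frame, ΔG = Σ complex − (Σ ligand + Σ receptor). Grouping follows
the component convention: electrostatic = Coulomb + H-bond + GB
solvation, vdW = vdW + π–π + self-contact, lipophilic alone; the groups
partition ΔG exactly by construction. Window summaries use the sample
(n−1) standard deviation — the summaries this mirrors do not state
which; n−1 is the safer estimator. Relative energies subtract the
minimum (most favorable system gets ΔΔE = 0). Per-residue
decompositions are plain (residue, kcal/mol) files; aggregation offers
set totals, magnitude-ranked top contributors (ties by residue number),
and a strict ">" threshold report. The sign convention is favorable =
negative throughout.

The bundled reference tables carry one internal inconsistency in their
source: the β-subtype total binding energy appears once as −131.2
kcal/mol in a concluding summary against −135.9 in the summary table
and abstract; the table value is used.

## Synthetic generators

The generators emulate the *statistical* structure the analyses assume,
not force-field physics: stationary Gaussian fluctuations about a fixed
mean geometry, planted block correlations
(Δr_i = σ_i(√ρ·z_b + √(1−ρ)·ε_i), giving intra-block correlation
exactly ρ), discrete conformational basins with exact frame counts
(largest-remainder apportionment, seed-shuffled order), deterministic
interaction schedules, and Gaussian energy terms whose ΔG mean and SD
follow analytically. The reference chain is a Cα/Cβ poly-alanine
zigzag with exact 3.8 Å Cα spacing (a straight line would make Cα-only
fits degenerate) or an ideal helix (1.5 Å rise, 100° twist, 2.3 Å
radius). Basin displacements are applied out of the backbone plane with
a period-4 sign pattern (+,+,−,−) that is mean-free and uncorrelated
with every rigid-body mode, so least-squares fitting cannot absorb the
planted separation. What the generators do **not** reproduce: solvent,
anharmonicity, realistic contact topology changes, correlated
noise spectra, or force-field energetics — so passing recovery tests
demonstrates correctness of the analysis arithmetic on data satisfying
its assumptions, not agreement with real MD output.

Problem sizes in the recovery suites (5000-frame ensembles, 1000-frame
mixtures and energy tables, 24-node planted graphs, ≤ 8-node oracle
graphs) are chosen so that Monte-Carlo error sits well inside the
stated tolerances while the whole suite completes in seconds on one
CPU.

## Known limitations

- The PDB reader accepts the multi-model dialect only (no mmCIF/PSF,
  no insertion codes); DCD input can be layered on the same contract
  but multi-model PDB is the reference dialect for all tests.
- Bond perception is by distance on the first frame; topologies whose
  bonding changes across frames (reactive trajectories) are out of
  scope.
- Ionic-group perception on ligands is geometric and approximate; no
  force-field charge assignment is attempted.
- Girvan–Newman is exact but O(m²n) per component; it is meant for
  residue-level graphs (hundreds of nodes), not atom-level ones.
- Crystallographic waters participate only in water-bridge detection;
  they are excluded from all default selections.
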