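# trajcomm

Post-simulation analysis of molecular-dynamics trajectories for
protein–ligand systems, built around the analysis stack used to study
how a pan-agonist ligand differentially activates nuclear-receptor
ligand-binding domains (full vs. partial activation of the PPAR α/β/γ
subtypes, read out through the conformation and flexibility of the
C-terminal activation helix, helix 12).

The package covers, as a tested reusable library with a thin CLI:

- **Superposition metrics** — Kabsch least-squares fitting, Cα RMSD time
  series, per-residue RMSF about the ensemble mean (two-pass fit), and
  sub-range (helix-12) RMSD against a crystal reference with a 0.5 Å
  histogram.
- **Conformational clustering** — average-linkage hierarchical
  clustering of frames on pairwise fitted RMSD with a merge cutoff
  (default 2.5 Å), centroid frames (most neighbors within the cutoff),
  and population percentages with a >1 % reporting filter.
- **Dynamical network model** — residue nodes (Cα; ligand at its
  heavy-atom centroid), contact edges for heavy-atom proximity within
  4.5 Å in ≥ 75 % of frames, cross-correlations
  C_ij = ⟨Δr_i·Δr_j⟩ / (⟨|Δr_i|²⟩⟨|Δr_j|²⟩)^½ of node displacements,
  edge weights w_ij = −log |C_ij|, Girvan–Newman communities (weighted
  betweenness, maximum-modularity stop), and critical nodes/edges
  connecting communities.
- **Normal modes** — covariance PCA of Cα displacements ("top 5 modes"),
  per-mode RMSF, block-consistency PCA, and single-structure
  anisotropic-network-model (ANM) modes (15 Å cutoff, uniform springs,
  six rigid-body zero modes identified and excluded).
- **Interaction profiling** — per-frame geometric detection of hydrogen
  bonds, hydrophobic contacts, ionic contacts and water bridges between
  protein and ligand; interaction fractions with the 30 % reporting
  threshold; rotatable-bond torsion histograms.
- **MM-GBSA bookkeeping** — per-frame binding energy
  ΔG = E_complex − (E_ligand + E_receptor) from term tables, component
  grouping (electrostatic = Coulomb + H-bond + GB solvation;
  vdW = vdW + π–π + self-contact; lipophilic), trailing-window mean ±
  SD, relative energies ΔΔE across systems, and per-residue
  decomposition aggregation. The published MM-GBSA summary and
  per-residue decomposition tables for chiglitazar bound to the three
  PPAR subtypes ship as reference data (`trajcomm.data`).
- **Synthetic data** — seeded generators for every input the pipeline
  consumes: Gaussian ensembles with planted correlation blocks,
  multi-state conformational mixtures with exact fractions, interaction
  schedules, and energy tables with known ΔG statistics.

The MM-GBSA energies themselves are *not* computed here — the package
consumes term tables and performs the downstream arithmetic.

## Worked example

Relative binding energies and decomposition aggregation on the bundled
published tables:

```python
>>> from trajcomm.data import load_reference_energies, load_reference_decomposition
>>> from trajcomm.energy import relative_energies, residue_set_total, top_contributors
>>> means = load_reference_energies().set_index("system")["de_mean"].to_dict()
>>> relative_energies(means)
{'alpha': 6.6, 'beta': 8.7, 'gamma': 0.0}
>>> gamma = load_reference_decomposition("gamma")
>>> top_contributors(gamma, 3)
[('ILE_341', -9.6), ('CYS_285', -5.6), ('ARG_288', -5.1)]
>>> residue_set_total(gamma, ["ILE_341", "SER_342", "GLU_343"])
-14.899999999999999
```

The γ subtype is the most favorable system (ΔΔE = 0), with the α and β
subtypes 6.6 and 8.7 kcal/mol less favorable — the ordering that tracks
the receptors' experimental EC₅₀ ranking. Ile341 anchors the β-sheet
contact region; the Ile341/Ser342/Glu343 trio contributes −14.9
kcal/mol in total.

Clustering a synthetic 70/30 two-state mixture from the CLI:

```sh
$ trajcomm synth two-state --residues 20 --frames 500 --fractions 0.7,0.3 \
      --separation 4.0 --noise 0.3 --seed 1 --out mix.pdb
$ trajcomm cluster mix.pdb --cutoff 2.5
cluster_id,population_percent,centroid_frame,n_members
0,70.0000,0,350
1,30.0000,8,150
```

The two planted basins (4 Å apart, 0.3 Å thermal noise) are recovered
at exactly their 70 %/30 % populations with the 2.5 Å merge cutoff.

An end-to-end run over a trajectory is configured with a flat YAML file
(`trajcomm run --config run.yaml`); every stage writes CSV/TSV outputs
plus a manifest echoing all parameters.

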