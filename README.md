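# bridgenet

Analysis toolkit for molecular-dynamics ensembles of two-body complexes
that stay associated while rotating against each other — the archetype
being the ribosome's 30S and 50S subunits during tRNA translocation. Given
one trajectory per conformational state, `bridgenet` answers the question
*how does the interface contact network keep the two bodies bound while
their contact surfaces shift by tens of Ångström?*

It is written for structural bioinformaticians and simulators who have a
set of state-resolved trajectories (e.g. started from cryo-EM-refined
intermediates) and want the full contact-network accounting:

- **Contacts & occupancies** — two residues are in contact in a frame when
  the minimum distance between any two of their atoms is below 3 Å
  (hydrogens included); per-state occupancy is the fraction of frames with
  the contact, and pairs reaching ≥ 1 % occupancy in at least one state
  are retained.
- **Contact clustering** — a two-stage algorithm groups interface residues
  into intersubunit contact clusters. Stage 1 works on ≥ 30 %-occupancy
  contacts: per-state connected components are pooled, sorted ascending by
  size, greedily accepted if disjoint, then rejected components are merged
  (single overlap) or their residues assigned by *closeness* — the sum over
  states of the occupancies a residue has with a cluster. Stage 2
  iteratively sorts residues with only sub-30 % contacts into the closest
  cluster; unconnected residues form a leftover group. Clusters whose mean
  interaction enthalpy stays below 1 % of the per-state total in every
  state are pruned.
- **Interaction enthalpies** — per cluster and state, the direct
  force-field sum over cross-group atom pairs
  `E = Σ f·q_i·q_j/r_ij + 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶]`
  with `f = 138.935458 kJ·mol⁻¹·nm·e⁻²`, Lorentz–Berthelot combination, no
  cutoff, vacuum dielectric. Ligand tables (tRNA–30S, tRNA–50S, tRNA–mRNA,
  mRNA–30S) expose the weakest-link bridging contribution of body-spanning
  ligands. A charge-sign-resolved Coulomb decomposition splits cluster
  energies into attractive (opposite-charge) and repulsive (equal-charge)
  residue-pair terms. Schlitter's formula gives an upper-bound
  conformational entropy from the mass-weighted covariance of fitted
  fluctuations.
- **Contact restriction** — each retained contact is binarized over states
  (occupancy > 0.25); a residue's restriction
  `R = 2/(n(n−1)) Σ_{i<j} r(c^i, c^j)` averages a co-occurrence indicator
  over its contact pairs. Low R marks residues that swap partners as the
  bodies rotate; cluster-level R is the mean over member residues.
- **Rotation angles** — signed angles of a mobile body about a declared
  axis (origin, direction, fit group), measured per frame after rigid-body
  (Kabsch) superposition, summarized as box-plot statistics per state.
- **Collective motion** — Cartesian PCA over concatenated, fit-superposed
  state trajectories; per-state projections on the leading modes,
  projection correlations between two selections (does a flexible helix
  arm track its partner protein?), and mode amplitudes.
- **Synthetic data** — a generator that emits toy two-body complexes (PDB +
  DCD + TSV parameters + YAML groups + JSON ground truth) with planted
  clusters, calibrated contact probabilities, a known rotation axis and
  per-state angles, charge-swap interfaces and a tracking arm, so every
  stage can be validated against known truth.

## Worked example

Generate a toy complex (three planted interface clusters, a flexible
tracking arm, a bridging ligand; three states spanning −2.7° to 16.3° of
body rotation) and run the whole pipeline:

```
bridgenet simulate --preset default --seed 11 --states 3 --frames 100 -o demo/sim
cat > demo/cfg.yaml <<EOF
topology: demo/sim/topology.pdb
parameters: demo/sim/parameters.tsv
config: demo/sim/config.yaml
output_dir: demo/out
ligands: [ligand1]
pca_selections: [[arm_tip, bodyA_core], [anchor, bodyA_core]]
correlate: [arm_tip, anchor]
EOF
bridgenet run -c demo/cfg.yaml
```

`demo/out/report.tsv` aggregates per-cluster enthalpy and restriction:

```
cluster  mean_R    H_state00   H_state01   H_state02
1        0.833333  -584.800295 -582.865877 -588.412121
2        0.666667  -594.604291 -578.363397 -581.683913
3        1.000000  -566.661045 -575.725816 -570.782740
4                    5.798157    5.711046    6.786776
```

Clusters 1–3 are the planted charged interface clusters: strong (≈ −580
kJ/mol) and steady across states, exactly the strong-and-steady pattern
the clustering is designed to surface. Cluster 4 is the neutral arm–anchor
contact; its tiny (+6 kJ/mol, pure Lennard-Jones) enthalpy is below 1 % of
the per-state total, so `clusters_pruned.tsv` drops it. `mean_R` is blank
there because a single contact carries no co-occurrence information.

`rotation_body_rotation.tsv` recovers the planted body rotation:

```
state    median   q1       q3       min      max
state00  -2.7142  -2.8945  -2.4617  -3.5896  -2.0161
state01   6.7571   6.5698   6.9648   5.5460   7.8669
state02  16.2825  15.9741  16.4895  15.5618  17.1829
```

— medians within 0.05° of the planted −2.7°, 6.8°, 16.3°. And
`projection_correlation.tsv` shows the arm tip tracking its anchor on the
rotating body (planted mechanism; r ≈ 0.995 in every state):

```
state    r
state00  0.994925
state01  0.995050
state02  0.995475
pooled   0.998628
```

Every stage is also available as a library call
(`bridgenet.contacts.occupancies`, `bridgenet.clustering.cluster_contacts`,
`bridgenet.energetics.cluster_enthalpies`, …) and as individual CLI
subcommands (`contacts`, `cluster`, `enthalpy`, `restrict`, `rotate`,
`pca`, `report`) that compose byte-for-byte with `run`.

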