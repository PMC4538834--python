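# Methods

## Scope and model

`bridgenet` analyses ensembles of the form *one topology, N named
conformational states, one multi-frame trajectory per state*. The model
system is a complex of two bodies (subunits) held together by a network of
non-covalent interface contacts while rotating relative to each other;
ligands spanning the two bodies (tRNA- and mRNA-like) may contribute to
the association. All analyses are solute-only: solvent, counter-ion and
water-mediated interactions are outside the model, and no
periodic-boundary imaging is applied — inputs are assumed whole and
unwrapped. Energies are reported as interaction *enthalpies*, never as
free energies.

Coordinates are Ångström everywhere downstream of loading. The parameter
table supplies per-atom point charges (e), Lennard-Jones σ (nm, converted
to Å once at load) and ε (kJ/mol), and masses (amu); no force-field
assignment logic exists — parameters must be provided, matched by
(residue name, atom name).

## Contact criterion and occupancies

Two residues are in contact in a frame when the minimum distance over all
atom pairs (hydrogens included) is **strictly below** the cutoff, default
3 Å. Occupancy per state is exact integer frame counting divided by frame
count. Retention keeps a pair iff occupancy **≥ 0.01** in at least one
state (inclusive, per-state maximum rather than pooled frames). Stability
for pattern overlap uses occupancy **> 0.75** (exclusive). These
inclusive/exclusive senses are deliberate and tested at the boundary.

Pattern overlap between two single-state contact patterns uses the
symmetric convention `|A∩B| / ((|A|+|B|)/2) × 100` over the stable sets;
when both sets are empty the result is flagged undefined rather than 0 or
100. The denominator is a design choice (it reproduces the 100 % and 0 %
extremes under any reasonable convention) isolated behind one function.

## Two-stage clustering

Stage 1 (contacts ≥ 0.30 occupancy in the given state):

1. per state, connected components of the contact graph (networkx);
2. pool all components, sort ascending by residue count; seed the common
   set with the smallest and greedily add each next component sharing no
   residue with an accepted one;
3. rejected components overlapping exactly one common cluster merge into
   it wholesale;
4. residues of components overlapping two or more common clusters are
   assigned to the cluster maximizing *closeness* = Σ over states of the
   occupancies of that residue's contacts with any cluster residue.

Stage 2: residues involved only in sub-0.30 contacts are assigned
iteratively — always the unassigned residue with the highest positive
closeness joins its closest cluster, and closeness is recomputed after
each assignment, so a residue can become reachable through a newly
assigned neighbour. Residues with zero closeness to every cluster form
one leftover group.

Tie-breaks (size sort and closest-cluster choice) use the lexicographic
(chain, residue number) of the smallest member, then state order; this
makes the output deterministic and membership invariant to state or input
permutation (only ids can differ, and ids are themselves fixed by the
rules below).

Closeness sums occupancies over **all** states; a per-state-maximum
variant was considered and rejected because the summed form uses all
evidence and makes the stage-2 fixed point independent of state order.

Pruning drops clusters whose |mean enthalpy| is below `floor` (default
1 %) of the summed per-cluster |mean enthalpy| in **every** state — one
strong state saves a cluster. After pruning, ids are reassigned by
descending state-averaged interaction strength; this numbering is a
presentation choice mirroring the field's convention of numbering bridges
by importance.

## Energetics

Group–group interaction enthalpy is the direct double sum of Coulomb
(`f = 138.935458 kJ·mol⁻¹·nm·e⁻²`, relative dielectric 1) and
Lennard-Jones terms with Lorentz–Berthelot combination (arithmetic σ,
geometric ε) and **no distance cutoff**. No cutoff keeps the additivity
identity `E(A, B∪C) = E(A,B) + E(A,C)` exact, which the tests rely on;
a zero interatomic distance is a hard error. Group order is canonicalized
internally so `E(A,B)` and `E(B,A)` are bit-identical.

The charge-pair decomposition classifies residues at residue level
(default: ARG/LYS +1, ASP/GLU −1, nucleotides −1, HIS 0, configurable)
and bins cross-part residue-pair Coulomb energies into attractive
(opposite signs), repulsive (equal nonzero signs) and neutral-involving;
the three bins sum exactly to the total cross-part Coulomb energy, which
is asserted against an independent oracle.

Ligand bridging tables report E(ligand–bodyB), E(ligand–bodyA),
E(ligand–mRNA) and E(mRNA–bodyA) per state plus the derived bridging
contribution E(ligand–bodyA) + E(ligand–mRNA) — the weak side of the
chain through which a body-spanning ligand actually holds the complex
together.

Hydrogen-bond energies use a pluggable monotone model of the
donor–acceptor distance, default `E(d) = −E₀·exp(−(d−d₀)/λ)` clamped to 0
beyond `d_max` (defaults E₀ = 10 kJ/mol, d₀ = 2.8 Å, λ = 0.5 Å,
d_max = 3.5 Å). The exponential is a stand-in behind a strategy
interface: any callable of distance can be supplied, and only the
documented properties (value −E₀ at d₀, clamp, monotonicity) are relied
on.

Schlitter's entropy
`S = (k_B/2)·ln det(1 + (k_B T e²/ħ²)·M^{1/2} C M^{1/2})`
is computed on the Cartesian covariance of the selection after rigid-body
fitting each frame to the segment mean (the selection is its own fit
group — this removes external rotation/translation), masses on the
diagonal, returned per mole in J/(mol·K). A non-positive determinant
raises with a condition-number report rather than returning garbage. The
estimate is an upper bound, used here only to check that enthalpy ranking
is not overturned by configurational entropy.

## Geometry

Superposition is the SVD/Kabsch least-squares fit constrained to proper
rotations (det = +1); mirror-related inputs keep a positive rmsd, and a
collinear fit set is an error. Rotation angles about a declared axis
(origin, unit direction, fit group, mobile group) are measured after
fitting the frame to a reference over the fit group: each mobile atom's
offset from the axis origin is projected onto the plane normal to the
axis and the angle is the unweighted mean signed angular displacement
versus the reference (right-hand rule about the axis direction). Atoms
within 1e-6 Å of the axis are skipped; all-on-axis is an error. The mean
projected-displacement form is exact on rigid rotations and degrades
gracefully under thermal jitter (the per-state mean over frames is the
recommended summary; jitter enters as ≈ σ/(r·√n_atoms) radians per
frame).

Axes are first-class inputs: the method deliberately does not try to
discover rotation axes, and the synthetic generator emits its ground-truth
axis in the same config format. The reference geometry for angle and
COM-shift measurements is the coordinate file's structure (the generator
writes the unrotated, noise-free geometry there).

Center-of-mass shift between two states superposes all frames of both
states onto one shared reference over a fit group (typically the opposing
body's core), takes per-state mean structures, and reports the
mass-weighted COM distance of the chosen residues — invariant to any
global rigid motion applied to either state's frames.

## Collective motion

PCA is unweighted Cartesian PCA of a selection over concatenated,
fit-superposed frames of all states. The fit reference is the ensemble
mean after one fit-to-first-frame / re-mean iteration — deterministic and
standard. Eigenvector signs are fixed (largest-magnitude component
positive) so projections are reproducible across runs. Projection
correlations are Pearson, per state and pooled; zero-variance segments
are flagged `None` rather than given a coefficient. Mode amplitude
converts the mode-1 projection range to centroid displacement by scaling
with the norm of the eigenvector's mean per-atom 3-vector; the
alternative reading (max pairwise atom displacement) is available by
combining projections with the eigenvector directly. Per-state mean
centroid deviations complement the range measure.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes,
not ribosome geometry: two rigid pseudo-atom rings (radius 25 Å, 8 beads,
±6 Å from the interface plane) as body cores, the mobile ring rotated per
state about the z-axis; interface clusters of 1-atom beads (ARG = +1e,
NUC = −1e, GLY/COR neutral; charged beads are pure Coulomb, ε = 0)
placed at ~18 Å radius. Defaults mirror the study conditions the method
is built for: per-state rotation angles spanning −2.7° to 16.3°, thermal
jitter 0.3 Å per coordinate per atom (a typical heavy-atom RMSF scale),
100–500 frames per state at toy scale.

Contact probabilities are calibrated by Monte-Carlo: for a target p, the
generator pre-samples the relative jitter distribution (50 000 draws) and
bisects the bead separation until the simulated below-cutoff probability
matches p; realized trajectory frequencies are recorded in the ground
truth and checked against binomial 3σ bounds. Degenerate targets (0, 1)
are placed far outside / at zero separation and must be realized exactly.

Presets exercise each downstream mechanism: `clusterable` (k star
clusters with a step-3 satellite, a stage-2 low-occupancy bead, a
state-specific cross-cluster bridge bead for step 4, and an isolated
leftover pair), `sliding` (a charged bead pairing with a +1 partner at
the rotation extremes and a neutral one at mid-rotation, next to a fully
locked cluster), `tracking-arm` (a tip bead sharing its anchor's
tangential driver; the `independent` variant decouples both driver and
per-state position, giving the correlation null), `bridging-ligand`
(a −1 ligand bead 2.5 Å from a +1 receptor on one body and 5.5 Å from
one on the other), and `default` (clusterable + arm + ligand).

What passing these benchmarks does **not** show: robustness to
force-field realism (bonded terms, many-atom residues), to solvent-
mediated interactions, to imperfect sampling of slow degrees of freedom,
or to periodic-boundary artifacts — real trajectories must be whole and
well-sampled before this analysis is meaningful.

## Numerical and design notes

- Problem sizes in the test-suite and acceptance runs (toy systems of
  ~20–60 beads, 3–5 states, 60–500 frames) are chosen as the smallest
  ensembles on which every code path and statistical bound is
  informative; all thresholds are the method's defaults, never tuned per
  run.
- Occupancy arithmetic is integer-exact before division; boundary
  comparisons (≥ 1 %, ≥ 30 %, > 25 %, > 75 %, < 3 Å) follow the stated
  inclusive/exclusive senses and are pinned by boundary tests.
- All-zero binarized contact vectors are excluded from restriction
  scoring (they would deflate R artificially); residues with fewer than
  two active contacts are excluded from cluster means rather than
  assigned a score, because a single contact carries no co-occurrence
  information.
- Every pipeline output carries the SHA-256 digest (first 16 hex digits)
  of the analysis configuration; the output directory is excluded from
  the digest so relocating a run does not change its provenance. No
  timestamps enter outputs; reruns are byte-identical.
- The CLI is a thin layer over the same stage functions the library
  exposes; subcommands compose byte-for-byte with the full pipeline.

## Known limitations

- Contact detection is O(atoms_A × atoms_B) per frame via a dense
  distance matrix — appropriate for interface-sized selections, not
  whole-system contact maps of very large complexes.
- The hydrogen-bond energy model is a configurable stand-in, not a
  published parameterization; conclusions should not rest on its absolute
  values.
- The restriction score is binary co-occurrence; no occupancy-weighted
  variant is provided.
- No time-lagged or independent component analysis; PCA only.
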