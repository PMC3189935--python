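# Methods

## Residue networks and topology parameters

An unbound protein is modeled as an undirected, unweighted graph: one node per
residue, represented by its Cα atom (or Cβ, with Cα standing in for glycine),
and an edge whenever the representative atoms of two residues lie within the
contact cutoff, 8.5 Å by default and inclusive (≤). Neighbor search uses a
k-d tree; an O(n²) distance scan is retained in the test suite as the oracle.
Non-standard residues are excluded by default (`standard_only`), and residues
missing the representative atom are dropped with a warning.

Four per-node parameters are computed (networkx under the hood; every one is
checked against an independent brute-force implementation in the tests):

- **closeness** `(N−1)/Σ_y d(x,y)` with hop-count shortest paths. On
  disconnected graphs, each component's value is scaled by
  `(n_comp−1)/(N−1)` (Wasserman–Faust) to keep values comparable across
  proteins; `wf_scaling=False` gives the unscaled within-component value.
  Isolated nodes score 0.
- **degree** as the fraction of the other `N−1` nodes connected (the raw
  count is available via `normalized=False`). The fraction is the default
  because the other measures are also size-normalized and values are
  compared across proteins.
- **betweenness**: fraction of all-pairs shortest paths through the node,
  endpoints excluded, normalized by `(N−1)(N−2)/2` so values lie in [0, 1].
- **inverted clustering** `1/clustering`, so that like the other parameters
  higher values track binding sites. Nodes with fewer than two neighbors or
  no triangles have no defined value: they carry NaN, never enter top-k
  selections, and contribute 0 to pose scores (a 1/0 sentinel must not
  dominate sums).

## Binding-site prediction

Predictions are the top-k (default 4) surface residues by one parameter,
restricted to residues whose value reaches a cutoff; when nothing qualifies
the case yields no prediction and is excluded from mean-PPV aggregation (the
companion "% cases with predictions" statistic reports how often that
happens). Surface means relative ASA > 0.1% — deliberately permissive,
essentially "any exposure at all" — with the threshold configurable.
Relative ASA divides the residue's in-context heavy-atom ASA by an embedded
table of per-residue-type maximal areas (theoretical Gly-X-Gly values of
Tien et al. 2013; unknown types fall back to the glycine reference with a
warning). Ties at the k-th value break by residue ID for determinism.

PPV is the percentage of predicted residues found in the true interface:
residues of the unbound protein (mapped by shared residue ID) with at least
one atom within 10 Å of the partner in the reference complex. The random
baseline draws k surface residues uniformly without replacement (default 100
repetitions); its expectation is the hypergeometric mean
`100·|truth ∩ surface|/|surface|`, which the tests verify the Monte-Carlo
estimate approaches at the 1/√n rate.

## Accessibility and the canonical SASA frame

Per-atom accessibility uses the Shrake–Rupley sphere-point method
(`biotite.structure.sasa`, element radii, 960 points for surface profiles,
240 for the desolvation term where only differences matter). Sphere-point
sampling is orientation-dependent, so all SASA evaluations first move the
atom cloud into a canonical principal-axis frame: eigenvectors of the
coordinate covariance, signs fixed by the third moment of the projections
(largest-component sign as fallback), third axis by cross product. This makes
accessibility — and therefore the desolvation energy — exactly invariant
under rigid motion of the input, at the cost of being undefined for exactly
symmetric point clouds (irrelevant for molecular inputs).

## Shape descriptor

Protein shape is summarized by the peak-to-peak extents of the Cα cloud
along its principal axes ("length of an axis" is read as an extent, not a
variance). Anisotropy is the extent of the most different axis — the one
deviating most, multiplicatively, from the mean of the other two — divided
by that mean. Below 0.7 the protein is oblate, above 2.0 prolate, otherwise
spherical. The multiplicative deviation rule matters: an additive rule
misclassifies thin discs whose two long axes differ moderately.

## Pose scoring

Docking poses are rigid transforms `x' = Rx + t` of the unbound ligand
(rotations checked orthonormal to 1e-6; offending poses are rejected with a
warning). The docking interface at contact distance d (default 15 Å, the
best-performing value; fully configurable) is the set of residues of either
partner with a heavy atom within d of any heavy atom of the other, buried
and surface residues alike. The network score of a pose is the sum of the
precomputed parameter values over both interface residue sets, each residue
counted once regardless of its number of atomic contacts. Contact-count
weighting exists behind a flag but is off by default — it degrades
rigid-body rescoring, where side chains are not in their bound
conformations. Profiles are computed once on the unbound partners and are
strictly pose-independent; scoring 10,000 poses never rebuilds a network.

## Energy score

The binding-energy score is a deliberately compact three-term model (the
term structure is the contract; reproducing any particular program's
numbers is a non-goal):

- electrostatics: Coulomb over inter-molecular heavy-atom pairs with
  distance-dependent dielectric ε(r) = ε₀·r (ε₀ = 4, configurable), each
  pair clamped to ±1 kcal/mol before summation;
- van der Waals: 6-12 Lennard-Jones, each pair clamped above at +1 kcal/mol
  (no lower clamp), total weighted by 0.1;
- desolvation: atomic solvation parameters times the ASA buried on binding,
  `Σ σ(element)·(ASA_complex − ASA_isolated)`.

Embedded parameters: per-element LJ radii/well depths (C/N/O/S), backbone
partial charges by atom name (N −0.42, CA +0.03, C +0.60, O −0.57) with
full/half charges on Lys/Arg/Asp/Glu side-chain termini, and
Wesson–Eisenberg-sign solvation parameters (carbon burial favorable at
+0.012 kcal/mol/Å², N/O burial unfavorable at −0.060). Hydrogens are ignored
throughout (united-atom treatment: rigid-body inputs rarely carry them);
atoms of other elements raise a parameter-assignment error naming the atom.
Only inter-molecular pairs are ever evaluated. External per-pose energy
tables (TSV) can substitute for this module entirely.

A consequence of the solvation signs worth knowing: a bare charged N/O pair
at contact is net *unfavorable* (polar burial penalty ~+3 exceeds the
clamped −1 electrostatics) — favorable toy complexes are apolar contacts.

## Combined scoring and the weight fit

Energy is lower-is-better; the raw network score higher-is-better. The
single sign convention lives in `combined_score`: `energy + w·(−network)`,
so "lower is better" governs every ranking. The weight is fitted by
exhaustive grid search (default 0.0–2.0, step 0.05) minimizing
`F(w) = Σ_m ln Rank_m(w)`, where `Rank_m(w)` is the 1-based rank of the
best-scoring near-native pose (ligand Cα-RMSD < 10 Å, strict) of case m;
cases with no near-native pose are excluded. Score ties break by pose_id,
making F deterministic; grid ties resolve to the smallest w; rank 1
contributes ln 1 = 0. F depends on scores only through ranks, so it is
invariant under any positive rescaling of a case's scores. Leave-one-out
cross-validation refits w with each case held out and reports whether all
folds agree — with a shallow F plateau (noisy energies), folds can select
neighboring grid points; on a symmetric ensemble they are provably
identical. A default w = 0.45 ships for users who skip fitting.

## Evaluation

Ligand Cα-RMSD is computed without superposition (poses share the receptor
frame), matching residues by ID. Top-N success is the percentage of cases
with a near-native among the N best-scoring poses, over cases owning at
least one near-native. Reports stratify by user-supplied complex type, by
unbound/bound RMSD with bins `< 0.5`, `[0.5, 1.5)`, `≥ 1.5` Å (the middle
bin is left-closed since the printed bounds overlap), by anisotropy class,
and by configurable interface-area bins.

## Synthetic fixtures: what they emulate and what they do not

The generator builds pseudo-proteins — self-avoiding chains of
glycine/alanine-like residues (N, CA, C, O, CB) with 3.8 Å Cα steps,
confined to ellipsoids at ~150 Å³/residue — and synthetic docking cases
around them. Defaults define the study conditions and were chosen once:

- receptors are thin oblate discs (100 residues, axis ratio 6). On
  near-spherical or thick bodies of toy size, a 15 Å docking interface
  swallows essentially the whole protein and no site is distinguishable;
  the thin-disc regime is also where surface-proximal high-closeness
  residues make the network score informative, mirroring where the method
  works best on real proteins (oblate ones);
- ligands are 24-residue spheres; 100 decoys per case; near-native fraction
  0.02 (at least one forced), reflecting the scarcity of near-natives in
  FFT-generated decoy sets — with abundant near-natives even a random
  ranking places one early and no scoring signal is measurable;
- every decoy, near-native or not, is built by the same slide-to-contact
  construction (direction + orientation sampled, ligand slid to a ~4 Å
  heavy-atom gap), so the two classes share identical contact-geometry
  statistics and labels carry no construction artifact; RMSD labels are
  computed with the package's own evaluator, making generator and evaluator
  mutually checking;
- the reference docking site is found by a 48-direction slide-to-contact
  search scored primarily by coverage of the top-closeness surface residues
  at the 10 Å truth cutoff and secondarily by the closeness content of the
  15 Å docking interface. The signal-strength dial blends this ranking with
  noise: at 1 the bound pose buries the best patch the geometry offers, at
  0 a random contact site;
- synthetic per-pose energies are `0.1·min(RMSD, 30) + noise·N(0,1)`, so
  the energy channel's informativeness is controlled independently of the
  network channel.

Passing tests on these fixtures demonstrate the machinery — graph
construction, centralities, interface detection, rank-based fitting — under
a geometry where the planted signal is known. They do not demonstrate
benchmark-level predictive performance on real complexes, which depends on
crystal structures, FFT sampling, and conformational change that the
pseudo-proteins do not model (no secondary structure, no sequence, no side
chains beyond Cβ).

## Numerical choices and problem sizes

Distance comparisons at cutoffs are inclusive. Altloc resolution keeps the
highest-occupancy copy (ties: altloc 'A' first); model 1 of multi-model
files is used. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the same seed reproduces every coordinate.
The acceptance script runs 12 synthetic cases of 100 decoys with
noise-dominated energies (sd 10) — a size at which the full pipeline,
including the leave-one-out refits, completes in well under a minute while
the planted signal remains clearly measurable.

## Known limitations

- Unbound→complex residue correspondence is by shared ID; mismatched
  numbering is reported, not aligned.
- The embedded charge/LJ/solvation set is coarse (element-level LJ,
  backbone-plus-termini charges); it honors the term structure and clamps,
  not any published force field's values.
- Pose generation (FFT sampling), clash filtering and flexible refinement
  are out of scope; poses are inputs or come from the generator.
- `clustering_inv` is undefined on triangle-free neighborhoods; analyses
  using it silently skip such residues, which on sparse graphs can be many.
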