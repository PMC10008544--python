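# Methods

## Scope and model of the data

The package analyses *conformer ensembles* of a single protein: an ordered
list of structure frames sharing one topology (same residues, atoms and
ligand groups), read from multi-model PDB files. A frame's polymer residues
are graph vertices; whole ligand groups (a corrinoid cofactor, an
iron-sulfur cluster, a substrate molecule) are additional single vertices
regardless of how many HETATM residues or atoms they span. Per-residue
confidence (pLDDT in [0, 100]) rides in the B-factor column, following the
convention of predicted-structure models, or in a separate confidence JSON
(pLDDT array plus optional predicted-aligned-error matrix).

Two sources of ensembles are treated identically: time-ordered trajectory
snapshots and unordered populations of independently predicted models. The
`source` tag is provenance only; no computation branches on it.

## Flexibility and concordance

* **RMSF.** Each frame is superposed onto the first frame over all Cα atoms
  (Kabsch), then `RMSF_i = sqrt(mean_t |r_i(t) − r̄_i|²)` with `r̄_i` the
  across-frame mean of residue *i*'s selected atom. Selection defaults to
  Cα; `heavy` averages per-atom RMSF over the residue's heavy atoms.
  Superposition is on by default because global drift or tumbling otherwise
  inflates every residue's apparent fluctuation; it can be disabled, which
  is also what the generator-recovery checks use, since the generator adds
  no global motion and the no-superposition estimate is then exactly
  unbiased.
* **AF2-score.** `AF2_i = (pLDDT_max − pLDDT_i) / (pLDDT_max − pLDDT_min)`,
  extrema over the profile itself — a reverse min–max normalization, so a
  high score means low confidence, i.e. predicted flexibility. A constant
  profile has no range; it maps to all zeros with a mandatory warning
  rather than an error, so pipelines running on truncated fragments do not
  abort. The score is invariant under positive affine rescaling of the
  input profile.
* **Concordance.** Sample Pearson r between two per-residue tracks, with
  the two-sided p-value from `t = r·sqrt((n−2)/(1−r²))` against Student-t
  with n−2 degrees of freedom (scipy's `pearsonr`, which implements exactly
  this). All residues enter by default; constant tracks are an error
  because the correlation is undefined. p-values are reported raw — one
  coefficient per system, no multiple-testing family.
* **RMSD series.** Per-frame Cα RMSD to a chosen reference frame after
  superposition; `tail_mean` summarizes the trailing
  `ceil(fraction · n)` entries as mean ± s.d. (population s.d.).

## Contact dialects and interaction networks

Two residue-distance definitions are implemented:

* `heavy_min` (default): `d_ij` is the minimum Euclidean distance over all
  heavy-atom (non-hydrogen) pairs of the two residues, cutoff 3.5 Å. The
  cutoff is the upper end of donor–acceptor separations for hydrogen bonds
  (2–3 Å for N/O pairs, ~3.5 Å for C–H···O), so an edge means a plausible
  direct interatomic interaction.
* `cbeta`: the classic Cβ–Cβ distance (Cα for Gly), cutoff 8 Å. Kept as a
  reference dialect; it can both miss contacts (long sidechains reaching
  across a gap) and invent them, which a regression fixture demonstrates.

Edges are strict: `0 < d_ij < cutoff`. Sequence-adjacent polymer pairs are
kept as edges but flagged `bonded`; an option removes them. Ligand groups
appear only in `heavy_min` mode (the Cβ dialect has no anchor atom for a
ligand; they are excluded with a warning). Vertices carry a residue class —
positive (Lys, Arg), negative (Glu, Asp), aromatic (His, Tyr, Phe, Trp),
other — used to annotate contact-frequency rankings.

Distance-map vs PAE-map agreement is quantified as the Spearman rank
correlation over strict upper-triangle entries. Rank correlation is the
deliberate choice: the two maps are on different scales (Å vs expected
error) and only the monotone pattern is comparable.

## Dynamic networks and contact frequencies

One RIN per selected frame (`stride` subsamples). For a ligand vertex, the
frequency table reports `100 · (#frames with edge) / n_frames` per residue,
sorted descending with ties broken by residue key, and the ligand's
per-frame polymer partner count as mean ± population s.d. (divide-by-n; at
the 100-frame scale used throughout, the n vs n−1 distinction is below
reporting precision, and the population convention keeps single-frame
ensembles defined). Threshold filtering is strict (`percent > threshold`).
An interaction is counted when any heavy-atom pair crosses the cutoff in
that frame — per-frame binary, no persistence requirement.

## Superposition and template-based ligand transfer

Rigid superposition is a direct Kabsch solve: SVD of the covariance of
centered paired coordinates, with the smallest singular direction
sign-flipped whenever the unconstrained optimum is a reflection — the
optimal rotation constrained to det = +1. Collinear or sub-3-point inputs
are rejected. Transforms compose associatively and are validated
(orthogonality and determinant to 1e-9) at construction.

Ligand transfer pairs template and model residues by Needleman–Wunsch
global alignment (match 1, mismatch 0, gap −1; traceback ties resolve
diagonal > up > left, making the pairing deterministic), superposes the
template onto the model over paired Cα atoms, and applies that single
rigid motion to every template ligand atom. Internal ligand geometry is
preserved exactly. This unweighted whole-chain superposition is the
package's documented simplification of distance-weighted iterative
structure alignment; the two coincide in the regime transfer is meant for
(near-identical sequences), and the Cα fit RMSD is reported because it
bounds the placement error. A clash check lists ligand–polymer heavy-atom
pairs under 2.0 Å (configurable) — the shortest plausible non-bonded
approach; an empty list is an acceptable placement.

## RMSD matrices and snapshot trees

All-pairs Cα RMSD after per-pair Kabsch superposition, computed once per
pair. RMSD after independent superpositions is not a metric, so no triangle
inequality is asserted — only symmetry, nonnegativity and a zero diagonal.
The matrix is converted to an unrooted tree by Saitou–Nei neighbor joining:
join the pair minimizing `Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`,
with the standard branch-length and distance-update formulas. Ties in Q
break on the lexicographically smallest sorted label pair (each active node
represented by its smallest leaf label), making output deterministic.
Negative branch lengths — possible on non-additive input — are clamped to
zero with a warning. NJ (not UPGMA) is used because the distances are not
ultrametric and NJ is exact on additive matrices, which the consistency
tests exploit: distances generated from random binary trees must be
inverted to the generating topology and branch lengths. Trees serialize to
plain Newick (6 significant digits; labels with reserved characters are
quoted).

## Synthetic ensembles: what they emulate and what they do not

No suitable public ensemble ships with the package, so the ground-truth
test bed is synthetic:

* **Base fold.** An idealized helical Cα trace (rise 1.5 Å, radius 2.3 Å,
  100°/residue — consecutive Cα spacing 3.83 Å) with N, Cα, C, O and Cβ
  pseudo-atoms per residue (no Cβ for Gly; Cβ offset 1.53 Å radially
  outward). Offsets were chosen so that no two non-bonded heavy atoms come
  within 2.0 Å; a helix rather than a random walk guarantees reproducible,
  clash-free geometry.
* **Jitter.** Frame *t* displaces all atoms of residue *i* by one shared
  isotropic Gaussian draw with per-coordinate s.d. σ_i (rigid-residue
  jitter). This makes inter-residue minimum distances fluctuate coherently,
  like sidechain motion, and gives the exact ground truth
  `RMSF_i = sqrt(3)·σ_i` (per-coordinate variance σ² in three independent
  coordinates). The default σ profile is a rigid core (0.5 Å) with linear
  ramps to flexible termini (2.5 Å over 10 residues) — the canonical shape
  of a folded globular chain.
* **Confidence.** `pLDDT_i = clamp(95 − a·σ_i + η, 0, 100)` with slope
  a = 10 pLDDT/Å and η ~ N(0, noise_sd²). With noise 0 the profile is an
  exact decreasing affine function of σ, so the AF2-score correlates with
  flexibility at exactly +1; `noise_sd` is the single knob that degrades
  concordance, emulating systems whose confidence is less informative
  about their actual dynamics.
* **Ligand schedules.** A small rigid 4-heavy-atom group is placed, in an
  exact count `round(f · n_frames)` of frames drawn without replacement,
  with its nearest atom `d_on` = 3.0 Å from the target residue's Cβ
  (Cα for Gly) along the direction radially away from the chain's
  principal axis, and `d_off` = 6.0 Å otherwise. Exact counts rather than
  Bernoulli draws make frequency recovery exact, not statistical. The
  radial direction keeps the ligand clear of residues on adjacent helical
  turns so the designed contact is the only designed contact. Ligand
  labels double as PDB residue names and are limited to three characters.
* **Determinism.** Everything is driven by `numpy` Generators seeded from
  the spec seed (ligand schedules additionally salt the seed with a CRC of
  the label); identical specs give bit-identical ensembles.

What the generator does **not** emulate: real backbone topology and
secondary-structure diversity, anisotropic or correlated motions, torsional
sampling, sidechain chemistry, solvent, or any physical energetics. Passing
the recovery tests therefore demonstrates that the estimators are correct
and self-consistent on data with known truth — not that the scientific
conclusions transfer to any particular real protein.

## Numerical choices and problem sizes

* PDB coordinates round-trip at the format's fixed-width 1e-3 Å; all
  geometric identity checks through files use that tolerance, in-memory
  checks use 1e-9 or better.
* Altloc resolution: highest occupancy, ties by altloc letter. Waters are
  always dropped; the networks contain no solvent vertices.
* pLDDT values outside [0, 100] are clamped with a warning.
* RMSF recovery uses 2000 frames (relative Monte-Carlo error of an RMSF
  estimate scales as 1/sqrt(2·n_frames) ≈ 1.6%, comfortably inside the 5%
  acceptance band); frequency and determinism checks use 100-frame
  ensembles of 30–60 residues; NJ consistency uses 200 random trees of up
  to 12 leaves. These sizes keep every check well-resolved while the whole
  suite runs in well under a minute per module.
* The batch driver isolates failures: one bad system (e.g. a single-frame
  ensemble, for which RMSF is undefined) reports its error in its row while
  the rest of the table completes.

## Known limitations

* The Cβ dialect cannot represent ligand vertices; mixed-dialect networks
  are deliberately not provided.
* Sequence pairing is global alignment only; grafting between genuinely
  divergent folds (where distance-weighted iterative alignment would
  dominate) is out of scope, as are docking, covalent attachment and
  protonation.
* Formal charges on ligand groups are stored metadata only (e.g. −2
  oxidized / −3 reduced for an Fe4S4 cluster with its four cysteines);
  no electrostatics is computed.
* mmCIF and binary trajectory formats are not read; multi-model PDB is the
  single structural dialect.
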