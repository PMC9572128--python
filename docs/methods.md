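# Methods

## Problem and model

Collision cross section (CCS, Å²) — the rotationally averaged gas-phase
cross-sectional area of an ion measured by ion mobility spectrometry — adds an
orthogonal identification dimension to high-resolution mass spectrometry in
non-target screening. `ccsfp` predicts CCS from structure alone using hashed
topological-torsion fingerprints as the only features and random forests as
the only learner, in two strategies:

* **direct**: one forest trained on the whole curated library;
* **class-based**: a forest classifier first assigns a chemical super class
  from the fingerprint, then a per-class forest predicts CCS.

Both are exposed as statsmodels-style model objects
(`SuperClassClassifier`, `CCSRegressor`) whose `fit()` returns a results
object carrying the fitted forest, the full cross-validation table, the best
hyperparameters and a `summary()`.

### Fingerprints

A molecule is encoded by its topological torsions: every walk of four bonded
atoms, typed by element, aromaticity and connectivity, hashed into a
fixed-length binary vector (default 1024 bits). Bits record *presence* of a
torsion type, not its count. The encoding is RDKit's hashed
topological-torsion generator with count simulation disabled; a folded bit is
the sparse torsion code modulo the vector length. Bit-level identity with any
other software's fingerprints is **not** a contract of this package — only
the length and the presence semantics are. Two edge cases worth knowing:
molecules without any 4-atom path (methane, isobutane) map to the all-zero
vector, and in three-membered rings the torsion walk closes on its first atom.

### Curation

Source libraries are flat CSV (`id,smiles,adduct,ccs,library,platform`).
Curation canonicalizes SMILES (RDKit canonical algorithm; raw forms are
retained), normalizes adduct spellings onto {[M+H]+, [M−H]−, [M]·, other},
and collapses *exact* duplicates — records identical in (canonical SMILES,
adduct, CCS rounded to 0.1 Å², the precision of published CCS tables; the
rounding is configurable). When libraries disagree on a duplicate, the record
from the first library in the user-supplied order is kept and the collapse is
logged. Records of the same ion with different CCS are all retained; they are
the inter-laboratory replicates whose relative standard deviation
(RSD = 100·sd/mean, sample sd with n−1 — replicate counts are small) the
replicate report summarizes, flagging keys above a configurable 10% RSD.
Only protonated, deprotonated and radical ions are kept for modelling: the
fingerprint carries no adduct information, so adducts such as [M+Na]+ are
filtered out (and counted). Remote compound-database retrieval is out of
scope; a local identifier→SMILES lookup table fills missing SMILES.

### Super-class consolidation

Raw libraries carry dozens of sparse super-class labels. Consolidation keeps
the k = 5 most populated classes (ties broken lexicographically) and folds
every other original class into one of them by Tanimoto similarity
(|A∩B|/|A∪B| over bit sets; 0/0 ≡ 0):

1. members of retained classes keep their label;
2. each member of a non-retained class finds its best match among
   retained-class chemicals; members whose best similarity ≥ the threshold
   (default 0.6, motivated by the similarity distribution — the large
   majority of random pairs fall below it) vote with their best match's
   class, and the *entire original class* follows the majority (ties go to
   the larger retained class). This per-class vote is the only rule that
   satisfies both requirements simultaneously: assignment by similarity and
   original classes never being split;
3. original classes with no above-threshold member are flagged; a fallback
   resolves them — nearest class ignoring the threshold (default), or a
   user-supplied mapping file standing in for expert manual assignment.

Raising the threshold can only grow the flagged set (checked as a property).

### Model selection

Both searches use scikit-learn grid search with seeded shuffled folds
(stratified folds for classification), scored by mean CV accuracy
(classification) or mean CV R² (regression):

| model | trees | min leaf | candidates | folds |
|---|---|---|---|---|
| classifier | 100–200 (5 values) | 2–15 (5 values) | 25 | 5 |
| regressors | 100–500 (10 values) | 5–20 (5 values) | 50 | 5 |

Grid values are evenly spaced integers over the stated ranges. Score ties are
broken toward fewer trees, then larger leaves (the cheaper, more regularized
model). The best candidate is refit on the full training split. A single
master seed (default 42, always logged) controls the train/test split, fold
assignment and forest randomness; rerunning with the same seed reproduces
identical predictions.

The train/test split for classification is stratified 80/20 with
largest-remainder rounding per class: the test total is
n − floor(0.8·n) and is apportioned by the largest fractional remainders.
Direct-regression splits are plain random 80/20 at record level; replicate
records of the same ion may straddle train and test, which mirrors how
merged inter-laboratory libraries are actually modelled. An optional
group-aware split (grouping by SMILES+adduct) is available for leakage-free
evaluation but is off by default.

### Evaluation

Regression reports R² (1 − SSres/SStot; undefined → NaN with a warning on
zero-variance targets), the **median** relative error
MRE = median(100·|ŷ−y|/y), residual quantiles and outliers, and within-x%
fractions at 1, 3, 5, 7, 8%. Classification reports accuracy, one-vs-rest F1
per class (0 when precision+recall is 0) and the confusion matrix
(rows = truth). Because a forest predicts by averaging training targets,
every regression prediction lies inside the training-target range; `predict`
asserts this on every call.

Feature importance uses the forests' impurity-based importances; each top
bit is annotated with example torsion paths found by re-enumerating torsions
of dataset molecules and matching the bit their hash sets, so a reported path
provably re-hashes to its claimed bit.

### Suspect-list application

A suspect list (`id,smiles`, NORMAN SusDat-shaped) is screened with both
strategies; unparseable rows go to a rejects file with reasons. Suspects have
no measured CCS, so the robustness diagnostic is the per-chemical difference
class-based − direct and the fraction of chemicals within ±25 Å².

## Synthetic data generator

The generator (`ccsfp.synth`) emulates the *shape* of a merged
multi-laboratory CCS library so every stage is testable offline. Ground truth
CCS is an exact deterministic function of structure,

    base = c0 + c1·(heavy atoms)^(2/3) + c2·(rings),   default (80, 25, −5),

an area-like scaling of a volume-like quantity spanning ≈140–280 Å² over the
generated size range; a measured record is base·(1+ε), ε ~ N(0, rsd/100).
Defaults, chosen once from the scale of real inter-laboratory data: noise
RSD 2% (published replicate medians are ≈1.4% within platform, 2–3% across
platforms), replicate rate 5% of molecules re-measured by a second simulated
laboratory (real merged libraries replicate ≈5% of their ions), and a uniform
mix of five structural families (heteroatom chains, benzenoids,
N-heterocycles, carboxylic acids, sugar-like polyols) standing in for super
classes.

Two design points matter:

* **Size-keyed composition.** Presence fingerprints discard counts, so a
  molecule assembled from many copies of one unit has a bit set that says
  nothing about its size — an early repetitive-template draft capped forest
  test R² near 0.65 no matter the hyperparameters. The generators therefore
  key backbone composition (atom pattern, branch count, head group, small
  markers) to molecular size, the way homologous series behave in empirical
  libraries where specific torsions are individually size-indicative (long
  acyl chains carry motifs absent from small metabolites). Randomness enters
  through branch positions and identities, which perturb bits without
  changing the heavy-atom count.
* **Families are fingerprint-separable by construction** (distinct cores and
  decoration grammars), which is what makes the classifier-separability
  property meaningful.

What the generator does *not* emulate: real CCS physics, conformational
effects, class-specific CCS distributions, adduct diversity (everything is
emitted as [M+H]+), or the label noise of curated taxonomies. Passing the
synthetic recovery tests therefore demonstrates that the pipeline is
implemented correctly and that the learner can extract a structural signal
from torsion bits — not that any particular accuracy will be attained on
empirical libraries.

## Problem sizes and numerical choices

* Parameter-recovery check: n = 2000 molecules, 2% noise, seed 42,
  80/20 stratified split, forest of 300 trees with leaf size 1 (a single
  pre-chosen point — the recovery property does not require a grid search);
  expected test R² ≥ 0.9 against the noise-free structural CCS and
  MRE ≤ 5%. Family-separability check: n = 1000, 150 trees, leaf 2,
  accuracy ≥ 0.95.
* Grid bookkeeping (exactly 25 and 50 candidates × 5 folds) is verified on
  small fixtures where the full grids run in seconds.
* Pairwise similarity summaries stream over row blocks (default block
  5000 molecules) so the dense pair matrix is never materialized for large
  sets; the gamma fit is method-of-moments and purely diagnostic.
* Tanimoto 0/0 (two empty fingerprints) is 0 by convention. Degenerate
  inputs fail loudly: empty datasets, non-positive CCS, thresholds outside
  (0, 1], classes smaller than the fold count, test classes unknown to a
  fitted model.
* `scripts/acceptance.py` reruns the whole synthetic study (n = 2000) at a
  caller-supplied seed with the single-point model settings above and writes
  every measured quantity to JSON.

## Known limitations

* Presence (not count) fingerprints are size-blind for repetitive
  structures; macromolecule-like inputs will under-predict, and the real
  studies this design follows report exactly that failure mode for
  oligosaccharides.
* Forest predictions cannot extrapolate beyond the training CCS range — by
  construction (and asserted).
* The consolidation vote assumes original class labels are coherent; a
  mislabelled original class is moved as a block.
* The manual step of expert class assignment is replaced by a mapping file
  or nearest-class fallback; results for flagged classes depend on that
  choice.
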