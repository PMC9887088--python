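# Methods

This note records the models, conventions and design choices behind
`remhom`, in the spirit of a methods section: what each component assumes,
which knobs matter, and what the synthetic test bed does and does not show
about real data.

## Problem setting

CATH classifies protein domains hierarchically
(Class.Architecture.Topology.Homologous-superfamily; dotted node strings
like `3.40.50.300`). The package targets the superfamily level in the
remote-homology regime: a query shares <20% sequence identity with every
training domain, so the classifier must rely on the structural/evolutionary
signal that protein language model (pLM) embeddings carry rather than on
direct sequence similarity. Superfamilies with too few non-redundant
experimentally characterised members to hold out are pooled into one
mixed-bag `other` class, which is an ordinary output class for training and
metrics but earns no hierarchy credit.

## Dataset construction

The build follows the standard leakage-free recipe:

1. Cluster PDB-derived domains at a low identity threshold (default 0.20).
   At production scale this is an external job (MMseqs2); the cluster-TSV
   adapter consumes its output. For fixture-scale work an internal
   longest-first greedy clusterer is provided, with a documented quadratic
   scale limit of a few hundred records.
2. Keep superfamilies with ≥2 cluster representatives (`min_pdb_members`,
   default 2 — the minimum that gives the test and validation sets one
   member each). The rest become `other`.
3. Split each superfamily's representatives between test and validation by
   seeded shuffle + alternation, guaranteeing both sets are non-empty per
   family. Gene3D (sequence-level) records form the training set.
4. Purge cross-set homologues at the identity ceiling: train is purged
   against test+validation, then validation against test. The test set is
   never reduced, so the benchmark stays fixed.
5. Randomly under-sample the `other` training class. No canonical retained
   size exists, so the default target (`"auto"`) is the median
   per-superfamily training count — it serves the step's purpose (reducing
   imbalance) without inventing a constant; any integer can be passed.
6. Optionally restrict to the k most populous superfamilies (ties broken
   lexicographically for determinism), dropping `other`.

**Sequence identity** is defined once, explicitly: matches / alignment
columns on an optimal global alignment under match +1, mismatch 0, linear
gap −1 (Needleman–Wunsch via Biopython's `PairwiseAligner`). Production
clustering tools use subtly different definitions (coverage constraints,
different denominators); fixing one definition keeps the leakage invariant
exactly testable. Where several optimal alignments exist the first reported
one is used; the identity is then one of the values achievable on an
optimal path, which the tests verify against an independent DP oracle.

## The classifier

`SuperfamilyMLP` is a single-hidden-layer softmax network:
input → dense(128) → ReLU → dropout(0.3) → batch norm → dense(K) → softmax,
trained with Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), batch size 256, categorical
cross-entropy, at most 200 epochs. Early stopping watches plain validation
accuracy: an epoch improves if it beats the best by more than 10⁻⁶;
after 20 non-improving epochs training stops and the best epoch's weights
(including batch-norm running statistics, momentum 0.9) are restored.
Inference disables dropout and uses running statistics, so duplicate inputs
give identical outputs. The latent representation (`transform`) is the
hidden layer after the dropout/batch-norm stage in inference mode — 128-D
by default — and is what supervised training distils out of the input
embedding.

Choices the architecture description leaves open, fixed here and
configurable: layer order dense → activation → dropout → batch-norm;
He initialisation for the hidden layer, Glorot for the output layer; loss
is categorical cross-entropy (the standard pairing with softmax). The
implementation is pure NumPy: at the few-thousand-sample scale the package
targets this trains in under a second on one CPU and keeps every step
reproducible for a given seed and thread count (documented contract: same
seed → same validation-accuracy trajectory within 10⁻⁶).

Baselines:

- **Logistic regression** — multinomial, lbfgs, max 5000 iterations
  (scikit-learn); non-convergence is recorded in the training log rather
  than raised.
- **Length-only network** — the same MLP on z-scored sequence length;
  controls for the possibility that embeddings merely encode length.
- **Class-prior random predictor** — labels drawn i.i.d. proportional to
  training counts; its expected accuracy against labels from the same
  prior is the collision probability Σpᵢ², the floor any learned model
  must clear.
- **Best-hit homology inference (HBI)** — per query keep the hits with the
  minimal e-value, take the one with the greatest percent identity,
  remaining ties resolved by lexicographic target id (the search tool's
  report order is not meaningful, so determinism requires an explicit
  rule). Queries without hits get a reserved `no_hit` outcome that is never
  a class label and always counts as an error. HBI confidence is 1 for
  resolved queries and 0 for `no_hit`; it is not a probability.

## Evaluation

Accuracy, macro-F1, multiclass MCC and balanced accuracy (macro recall),
averaged over the labels present in the true vector. Macro averaging is the
default because a single F1 is reported alongside balanced accuracy,
implying unweighted class treatment; the convention is recorded in every
report and switchable to weighted. Confidence intervals: resample the
(true, predicted) pairs with replacement `n_boot` = 1000 times and report
1.96 × bootstrap SD as the 95% half-width — predictions are fixed, only the
evaluation sample is resampled.

Calibration: for each threshold t, coverage is the fraction of predictions
with max probability ≥ t and error rate the fraction of those that are
wrong. Zero-coverage thresholds report error 0 with an explicit flag (kept
finite for plotting; the flag stops threshold selection from using them).
`threshold_for_error` returns the smallest threshold meeting a target error
rate with non-zero coverage and raises an explicit error when none does.

Hierarchy agreement gives misclassified domains partial credit when the
predicted node shares the Class (first field), Architecture (first two) or
Topology (first three) with the truth; `other`/`no_hit` earn nothing.

## Structure-based validation

AlphaFold models are screened with four rules (a domain is problematic if
**any** fires): mean per-residue pLDDT < 90; fewer than 3 secondary
structure elements; longest stretch of residues under 70 pLDDT covering
more than ⅓ of the domain; disorder (DSSP state `-`) above 70%. Conventions
fixed here: the per-domain quality scalar is the *mean* pLDDT over residues
(the per-model value distributed with the AF2 database is the residue
mean; median is available by configuration), and a secondary-structure
element is a maximal DSSP run of helix states (H/G/I) or strand states
(E/B) of length ≥3 — one- and two-residue segments are treated as
assignment noise. pLDDT is read from the B-factor column of the CA atom in
PDB/mmCIF files (gemmi); DSSP strings come from classic DSSP output or are
supplied directly, so no third-party binary is needed at test time.

SSAP validation: a predicted superfamily match is validated when the SSAP
score reaches the class-specific floor — 71 (mainly-α, class 1), 66
(mainly-β, class 2), 69 (α–β, class 3) — **and** the structural overlap is
≥60%. All comparisons are inclusive (a score exactly at the threshold
passes); this single convention is tested at the boundaries. Overlap is
taken as the fraction of the smaller domain covered by the alignment, as a
fraction in [0, 1], with a flag to accept percentage-scale input. CATH
classes without a published threshold (class 4+) return an explicit
`no_threshold` outcome. The closest relative per query is the maximal SSAP
score (ties: larger overlap, then lexicographic target id), and score sets
are compared by five-number summaries plus the difference of means. SSAP
itself runs externally; the module consumes its tabular results.

## Conservation analysis

Columns of a superfamily alignment are scored by
(1 − H/log 20) × non-gap-fraction, where H is the Shannon entropy of the
column's amino-acid frequencies with gaps excluded. A gap-free conserved
column scores 1, a gap-free maximally diverse column 0, and the non-gap
damping prevents sparse columns from scoring as conserved. This is a
transparent substitute for the Valdar-style scorecons score (which uses
stereochemical similarity matrices); it preserves the ordering behaviour
the analysis needs, is tagged in every profile's `method_tag`, and native
scorecons output can be loaded as a drop-in alternative profile source.
Alignment informativeness is summarised by a diversity-of-positions (DOPS)
substitute — the percentage of distinct column scores at 3-decimal
resolution — with the conventional ≥80 informativeness gate exposed in
configuration. Conserved columns (score ≥ 0.7 by default) are mapped to
query residues by gap-skipping, and mutation sites are assessed by minimal
residue-index distance to a conserved site (default window ±5). Proximity
is sequence distance; 3-D distance is an extension point, not a default.

## Synthetic test bed

`make_synthetic` emulates pooled pLM embeddings with planted class
structure. Class centroids are mutually orthogonal directions scaled by
separation/√2, so every centroid pair is exactly `separation` within-class
standard deviations apart (the within-class noise is isotropic unit
Gaussian); members are centroid + noise. The optional `other` class models
the heterogeneous mixed bag: each member sits on its own random centroid
(random direction, radius uniform within the named-centroid shell) plus
unit noise — diffuse, harder than the named classes, but learnable. In
high dimension random directions are near-orthogonal to the named
centroids, so the mixed bag does not collide with named classes by
construction. Matching domain records carry random sequences with
class-correlated lengths, giving the length-only baseline genuine signal.

The reference study conditions used throughout the tests and the
acceptance script are 20 named classes + `other` at 5% of the named total
(i.e. the same size as one named class), 64 dimensions, 100 members per
class, separation 8 for the separable regime and 0 for the null control,
with a 60/20/20 split. These sizes keep every model's training time in
seconds while leaving enough test samples (~420) for metric CIs of ±2
points.

What the synthetic bed does **not** capture: real embedding spaces are
anisotropic with class-dependent covariance and nested hierarchy structure;
real superfamily sizes are heavy-tailed rather than balanced; real
sequences determine their embeddings (here the two are independent); and
real identity distributions are not controlled by disjoint alphabets.
Passing tests therefore demonstrate correctness of the pipeline's
mechanics and decision rules, not benchmark-level performance on CATH —
the published CATH-scale numbers require database downloads and pLM
inference far outside a test suite.

## Numerical conventions

- Probability rows sum to 1 within 10⁻⁶; argmax/max-probability
  consistency is enforced at construction.
- Batch-norm variance guard ε = 10⁻⁸; log guard 10⁻³⁰⁰ in the loss.
- Embedding stores are 64-bit by default so save/load round-trips are
  exact; 32-bit is an explicit option.
- All stochastic operations (shuffles, under-sampling, dropout, bootstrap,
  random predictor, synthetic generation) take explicit seeds and are
  reproducible; dataset serialization is byte-deterministic.
- Degenerate inputs have defined behaviour: single-record length features
  use an SD guard of 1; all-gap alignment columns score 0 with a warning;
  empty conserved sets yield a flagged no-neighbour report; zero-coverage
  calibration bins are flagged rather than NaN.

## Known limitations

- The internal clusterer and purger are all-pairs quadratic — fixture
  scale only, by design; production clustering/search is delegated to
  MMseqs2/BLAST via the tabular adapters.
- The entropy conservation score does not numerically reproduce scorecons
  values (e.g. published per-residue scores); use the scorecons adapter
  when exact values matter.
- HBI consumes existing hit tables; it does not run BLAST.
- The MLP is CPU/NumPy; no GPU path, no ensembles, and no support for
  training at the million-sequence scale of full Gene3D.
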