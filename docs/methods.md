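# Methods

## Canonical tetranucleotide signatures

A metagenome's signature is built from all width-4 windows (step 1) of its
unassembled reads. Windows containing any character outside {A,C,G,T}
(case-insensitive) contribute nothing. Because shotgun sequencing samples
both strands at random, a 4-mer and its reverse complement carry the same
information; counting collapses the 256 raw 4-mers onto 136 canonical
equivalence classes (the canonical representative is the lexicographic
minimum of the pair; 16 classes are self-complementary, and
(256 − 16)/2 + 16 = 136). Reads are processed single-strand only — the
canonical collapse makes counting the reverse strand redundant — and
counting is exact (a 136-bin histogram), with no sketching.

Counts are converted to frequencies fᵢ = cᵢ/Σc. Naturally occurring
metagenomes are assumed to contain every tetranucleotide, but tiny inputs
(including synthetic fixtures) can miss classes, which would make the
ratio features undefined. The default `add_one` policy therefore adds one
pseudocount to *every* class when any class is zero (logged at INFO), so
the smoothing is uniform and the frequencies still sum to 1; a strict
`error` policy is available and names the offending classes.

The feature vector is the 136 frequencies followed by one ratio fᵢ/fⱼ per
unordered pair (i < j in class order), 9,316 features in total with stable
names (`freq:AAAA`, `ratio:AAAA/AAAC`, …). Ordered ratios would be
redundant — the reverse ratio is the reciprocal and adds no discriminative
information to a linear discriminant up to monotone transform — so only
the unordered set is emitted, with the lexicographically earlier class as
numerator. Frequencies are stored as fractions (sum 1), not percentages;
ratios are scale-invariant and the ordination is unaffected by a uniform
per-feature rescale (a property the tests assert).

## Ordination

Linear discriminant analysis with scikit-learn's SVD solver. With 9,316
features and a few hundred samples the within-class scatter is singular,
and the SVD (least-squares) formulation handles p ≫ n without forming or
inverting the scatter matrix; no shrinkage parameter is needed. The first
two discriminant axes are the diagram coordinates (with two classes there
is a single axis and the second coordinate is 0). Axis signs are arbitrary
in LDA, so each axis is flipped, if necessary, to give the
lexicographically first class a nonnegative mean coordinate — outputs are
then fully determined by the input.

Held-out evaluation uses a stratified 80/20 split (seeded), refits on the
training portion, and reports accuracy plus class-weighted precision and
F1 (labels can be heavily imbalanced in real corpora; weighting is the
conventional single-number summary). The projection used for plotting is
refit on all samples after evaluation.

## KNN phase map

Phases are mapped on a grid (default 200×200 cells over the coordinate
bounding box expanded by a 5% margin, both configurable) whose cell
centres are classified by unweighted majority vote among the k nearest
metagenomes in Euclidean coordinate distance. Majority ties — certain at
even k — are broken by the smallest summed distance from the query to the
tied class's voters, then lexicographically by group key, so the map is
deterministic. k clamps to the number of samples. The corpus-scale default
is k = 500; desk-scale runs in this repository use k ≈ 4% of n (e.g. k = 8
at n = 200), the same neighbourhood fraction that k = 500 represents in a
~12,000-metagenome corpus. Per-sample phase assignment classifies each
sample at its own coordinates (not via its containing cell) and records
concordance with its declared label.

## Abundance overlays and statistics

Identifier counts parsed from GFF3 column-9 attributes (default keys
`cog`, `ko`, `pfam`, `ec_number`; configurable, since annotation-pipeline
dialects differ) are normalised to counts per 10⁹ assembled bases. A
sample without an annotation file is missing (NaN) and hidden from
overlays — missing is an availability fact, zero a biological claim; a
gene absent from an annotated sample is a true zero. Statistics use
present values only (listwise per gene).

Welch's one-way ANOVA (heteroscedastic, Welch–Satterthwaite df) and
Games–Howell post hoc tests are implemented directly: for groups i, j,
q = |mᵢ − mⱼ| / √((vᵢ/nᵢ + vⱼ/nⱼ)/2) is referred to the studentized-range
distribution (scipy's numerical quantiles; agreement with an independent
reference implementation is asserted to 1e-6 in tests). Pairings use the
Welch two-sample two-tailed t-test. Stars are ≤-thresholds exactly:
\* 0.05, \*\* 0.01, \*\*\* 0.001. Degenerate groups (n < 2 or zero
variance) are rejected by name rather than silently propagated.

The overlay maps abundance linearly onto [0, 1] within an automatic or
user-supplied range, clipped; `heat_midpoint` applies a piecewise-linear
rescale that sends a chosen abundance to colormap position 0.5, the static
counterpart of an interactive heat slider.

## Importance ranking

Random forests (default 500 trees, unlimited depth, √p features per split,
seeded; all configurable) are trained on a stratified 75/25 split and
features ranked by mean decrease in impurity, ties broken lexicographically.
Per-ecosystem lists come from one-vs-rest forests — a defined per-class
score, where multiclass impurity importances are not class-attributable.
Direction tags compare the class mean against the rest-of-data mean on the
same zero-imputed matrix the forest sees ("abundance" when greater, else
"sparsity"). Missing abundances are imputed as zero for the model only;
missingness tracks annotation availability, not biology, and the held-out
accuracy is reported alongside every list.

## Synthetic cohorts

Each ecosystem group is an order-3 Markov chain over {A,C,G,T}: canonical
4-mer frequencies are exactly its sufficient statistics, and the
stationary tetranucleotide distribution is computable in closed form (the
stationary vector of the induced 64-state 3-mer chain times the
conditional next-base probabilities, collapsed over reverse complements) —
an analytic oracle the tests compare empirical counts against. All groups
share one base transition table (logit scale 0.4, i.e. moderately
non-uniform composition); each group adds logit noise of scale
`separation`, so separation 0 is an exact null and pairwise divergence
grows monotonically with it.

Study-condition defaults: 5 groups × 40 samples, 300 reads × 150 bp per
sample (a typical short-read length; ~44,000 4-mer windows per sample,
enough that sampling noise in each frequency is a few percent),
separation 0.25 (comfortably distinguishable groups while keeping
within-group overlap realistic), `assembled_bases` = reads × length. Reads
start from a uniformly random 3-mer context, so the first few windows of
each read are slightly off-stationary; the effect is far below sampling
noise at these read lengths.

Gene counts are negative binomial with variance μ + 0.3μ² (Poisson at
dispersion 0) and mean = base mean (default 50) × per-group multiplier, so
the unequal-variance statistics pathway is exercised with realistic
overdispersion. GFF3 fixtures emit one CDS line per identifier occurrence.

What the generator does *not* emulate: sequencing error, quality scores,
GC/coverage bias, real taxon genomes, or shared k-mer structure between
ecosystems. Passing tests therefore demonstrate correctness and
recoverability of the method's machinery under its own model assumptions,
not performance on real metagenomes.

## Calibration checks

The Games–Howell procedure is calibrated family-wise: over simulated null
datasets (3 groups, n = 15 each), the fraction of datasets with *any*
significant pair at α = 0.05 sits at the nominal rate (the per-comparison
rate is necessarily lower, ≈ α/3 for three groups). The null cohort
(separation 0) classifies at chance; the study cohort is expected to reach
≥ 0.9 on all split metrics and ≥ 95% phase concordance. These quantities
are recomputed from scratch by `scripts/acceptance.py`.

## Known limitations

- The SVD solver's discriminant directions are not unique under exact
  within-class degeneracy; determinism holds for fixed input order, which
  is what the pipeline guarantees.
- Grid classification is brute-force O(cells × n); adequate for desk-scale
  and corpus-scale-with-patience, but no spatial-index performance
  guarantees are made.
- Only k = 4 is exposed; the counting internals do not generalise to other
  k in the public surface.
- GFF3 parsing counts attribute values only; feature hierarchy is not
  validated and SAM/BAM input is out of scope.
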