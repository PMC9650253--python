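# Methods

This note documents the statistical procedures implemented in
`omnirule`, the choices made where the underlying protocol is
genuinely open, and what the synthetic benchmarks do and do not
demonstrate.

## Composition normalisation

Omics tables are treated as compositions: after optional scaling to an
internal-standard feature (the standard row is removed afterwards —
once every sample has standard = 1 it is uninformative), each sample
column is divided by its total.  All downstream methods therefore see
relative, not absolute, abundances; this matches how both NMR
region-of-interest tables and amplicon-derived taxon tables are
usually analysed, and it is the only normalisation the pipeline
assumes.  `composition_normalize` is idempotent and scale-invariant:
normalising to the standard first and renormalising changes nothing
relative to renormalising the standard-free table directly.

Degenerate inputs fail loudly: a non-positive standard or an all-zero
sample raises an error naming the offending sample.

## Cutting-strength log fit

Muscle texture curves (force in N against displacement in mm) are
summarised by ordinary least squares on `force = A·ln(x) + B`, so `A`
(N per log-mm) captures how steeply resistance grows and `B` (N) is
the force at unit displacement.  Displacements must be strictly
positive; two distinct points determine the line exactly.  The exact
axis convention of the original texture protocol is not fully
specified in the literature this mirrors, so the regressor is
displacement by default and configurable — the fit itself is standard
OLS either way (`numpy.polyfit` on `ln x`).

## Extreme-sample rule

Gut profiles occasionally collapse onto one or two taxa (e.g. an
individual whose sequenced content is essentially a single phylum).
Such samples dominate any distance-based clustering, so they are
removed before i-means.  The narrative omission reported for such
cases is formalised as: drop a sample when its `max_mass_features`
(default 2) largest features carry at least `mass_threshold` (default
0.99) of its total.  Both knobs are exposed because the rule is a
formalisation, not a published threshold.  Dropped samples keep their
row in the transaction set (with no taxa items) so cross-omic mining
still sees them.

## i-means: cluster number by classifier accuracy

For each candidate K (default 2–6), samples are partitioned with
K-means (k-means++ seeding, 10 restarts, best inertia) and the
partition is scored by how well a random forest can recover it on
held-out data: 5 stratified 70/30 splits, mean ± sd of test accuracy.
The chosen K is the **largest K with mean accuracy ≥ threshold**
(default 0.9); if none qualifies the procedure returns K = 2 with an
explicit fallback flag and warning.  The threshold rule is the
simplest monotone formalisation of the underlying idea — add groups
until the correct-answer rate gives out — and is configurable.

Unstated details of the original protocol were resolved as follows
and are all toggleable:

* **Feature scaling.** Features are standardised (zero mean, unit
  variance) for K-means only; the evaluation forest sees the raw
  composition table.  Standardising for the geometric step is
  conventional; forests are scale-free anyway.
* **Validation scheme.** Held-out stratified splits rather than
  resubstitution or out-of-bag, because resubstitution accuracy of a
  fully grown forest is ~1 for any labelling and cannot select K.
* **Importance.** Mean decrease in impurity (the classic default of
  the R random-forest implementation), averaged over the evaluation
  repeats at the chosen K; permutation importance is available.
* **Label numbering.** Classes are renumbered 1..K by descending size
  for stable reporting.
* **Degenerate partitions.** A K whose partition contains a cluster
  of fewer than 2 samples cannot be stratified; its accuracy is
  recorded as NaN and it never qualifies for selection (direct calls
  to `evaluate_partition` raise instead).
* **Forest size.** 100 trees per repeat — accuracy estimates are
  already stable at that size for tables of this shape, and the K
  scan fits 25 forests per omic.

## Two-group comparison

`classify_two_groups` mirrors the i-means evaluation machinery for a
fixed two-group labelling (e.g. one clade versus a pooled reference):
repeated stratified splits, held-out accuracy (reported per class and
overall — the overall value is the test-share-weighted combination of
the per-class values), and an averaged impurity importance ranking.
Whether published "100 %" classification figures are held-out or
resubstitution is usually unstated; here they are held-out, which is
the conservative reading.  Boxplot-style five-number summaries use
linearly interpolated quantiles.

## Rank-quartile discretisation

Numeric values become transaction items through ranking only, so any
strictly monotone transform of a variable yields identical items:

* a quarter is `⌊n/4⌋` entries (configurable to `⌈·⌉`), which
  guarantees High and Low never overlap and gives exactly equal High
  and Low counts on distinct values;
* phenotypes (length, weight, A/B, lipid, collagen) are ranked within
  strain, so "High" means high for that strain; strata smaller than 4
  yield no items (with a warning) rather than unstable ones;
* omics features are ranked within each individual sample ("ranking
  within an individual" read literally); the alternative reading —
  ranking each feature across samples — ships as mode
  `across_samples`, with no claim about which the original protocol
  meant;
* ties that straddle a quartile cut suppress High/Low for the whole
  tied block, with a warning.  This is conservative and makes the
  encoding independent of input order; it is also the one case where
  High and Low counts can differ.

Items are namespaced (`nmr:ROI.7=High`, `pheno:weight=Low`,
`habitat=lake_or_pond`, `NMR_class=2`) so variables from different
tables can never collide, and NULL labels produce no item.

## Apriori

Frequent itemsets are mined with the classic level-wise algorithm:
candidates at level k are built by joining level-(k−1) itemsets that
share a (k−2)-prefix, pruned by downward closure, and counted exactly
against a boolean incidence matrix (a small tolerance, 1e-9 below the
requested count, absorbs float representation of `min_support · n`).
The result is complete and exact; the test suite checks itemsets,
supports and every rule metric against a brute-force enumerator to
1e-12 across randomised basket sets.

Rules A → C are generated from every frequent itemset of size ≥ 2 and
every non-empty proper antecedent subset, filtered by confidence, and
finally by **lift strictly greater than 1** ("over 1" read literally;
lift exactly 1 is independence and is dropped).  Support and
confidence thresholds of the original mining run are unreported
upstream, so the defaults (0.1 and 0.5) are explicit package
assumptions, always visible in configs and manifests.  Maximum rule
length defaults to 4 items; rules are ordered by lift, then support,
then lexicographically, so output files are reproducible.  Tightly
concentrated compositions make many within-sample tiers nearly
constant across samples, and the number of rules then grows steeply
with rule length — pipeline-scale runs and the examples therefore
mine pairs (`max_len = 2`), which is also the granularity the rule
network displays.

## Rule network

Each rule contributes a directed edge from every antecedent item to
every consequent item; parallel contributions are merged keeping the
maximum lift (with that rule's support and confidence) plus a
multiplicity count, so no arity information is silently lost.  Nodes
carry namespace and level attributes for colouring.  Ego subgraphs
take all nodes within a given number of undirected hops of the focus
items.  Export is GEXF (Gephi's native format) or GraphML via
networkx; community detection and layout are deliberately left to the
downstream viewer.

## Synthetic data

The generator emulates the statistical structure the analysis
assumes, not the instruments:

* **Compositions** are Dirichlet draws (gamma normalisation) — the
  simplest simplex-respecting model.  Per-feature base concentrations
  are U(0.5, 1.5) scaled by `concentration` (default 50, i.e. ~15 %
  within-cluster CV per feature, a plausible biological spread for
  abundant signals); per-sample log-normal jitter (`noise_sd`,
  default 0.1) adds measurement-like noise.
* **Clusters**: each of k clusters inflates its own disjoint set of
  discriminative features (5 of 233 NMR regions, 2 of 21 taxa) by
  `1 + separation` (default 8).  Default cluster weights give one
  dominant cluster ~65 % of the samples and split the rest evenly
  (≈ 0.175/0.175/0.65 at k = 3), emulating the strongly unbalanced
  group sizes of real cohorts.  Balanced clusters were rejected at
  design time: combined with dispersed Dirichlet noise they make an
  over-split partition spuriously easy to classify, defeating the
  accuracy-drop principle i-means relies on; extremely unbalanced
  weights were rejected too, because a cluster of fewer than ~15
  samples is itself hard to classify at the true K.
* **Strains and metadata**: samples are spread over up to seven
  salmonid species; habitat (river / lake_or_pond / sea) is sampled
  from per-strain preferences, water type follows habitat.
* **Phenotypes** are normal per strain with per-strain mean shifts,
  so within-strain ranking is meaningful.
* **Planted rules**: for samples carrying a metadata item, the target
  feature's value is resampled so its within-sample rank lands inside
  (probability p) or outside (1 − p) the relevant quartile tier; the
  empirical conditional frequency converges to p.
* **Extreme mode** plants one sample with ~99.5 % of microbiota mass
  on two taxa, exercising the omission path.
* The **two-group benchmark** draws both groups from one tight
  Dirichlet baseline on a condensed 40-region panel and gives group A
  a marker with a dominant share U(0.2, 0.4) that group B lacks
  entirely — the idealised analogue of a single highly abundant
  clade-specific metabolite.  The dominance matters: a sqrt-mtry
  forest on a wide panel rarely samples a weak lone marker, so
  "disjoint support" alone does not imply perfect held-out accuracy.

Everything is a pure function of the config (including its seed);
identical configs give bit-identical tables, and CSV round-trips are
exact (reads use round-trip float parsing).

What the generator does **not** emulate: NMR spectra or peak overlap,
read-level sequencing noise, phylogenetic covariance among taxa,
strain-by-habitat confounding, or correlated phenotypes.  Passing
benchmarks therefore demonstrate that the machinery recovers the
structure it is designed for — not that any particular biological
conclusion would replicate on real fish.

## Pipeline and reproducibility

The pipeline validates its YAML/dict config strictly (unknown keys
rejected, defaults logged when used), derives one independent seed
per stage from the single global seed via
`SeedSequence([seed, stage_index])`, never mutates inputs, and writes
a manifest with every parameter, per-stage seed and SHA-256 digest of
every artifact; identical configs yield identical manifests.

## Problem sizes

Benchmark runs use synthetic studies at the modelled dimensions
(233 NMR regions, 21 taxa, ~120 fish; 200 fish for rule-recovery
runs), with 20 seeds per recovery-rate estimate and 5 classifier
repeats throughout; mining benchmarks use pair rules on vocabularies
of a few hundred items.  The oracle-equivalence checks run at ≤ 8
items × ≤ 25 transactions, where full enumeration is exact and cheap.

## Known limitations

* Support/confidence defaults are assumptions; published rule counts
  from undeposited data are not reproducible targets.
* The K-selection threshold (0.9) is a formalisation of a narrative
  criterion; very noisy data may warrant lowering it.
* Impurity importances are biased toward high-cardinality/continuous
  features; permutation importance is available where that matters.
* Apriori is exact but not optimised for very low support on large
  vocabularies (no FP-growth variant).
* The conservative tie policy can leave tied blocks unlabelled, and
  constant features never produce items.
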