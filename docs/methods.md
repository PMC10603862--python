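# Methods

This note documents the models, rules, and numerical choices behind
`semflow`, and what the synthetic study conditions do and do not show.

## Knowledge representation

All persistent state is a set of subject/predicate/object triples split
into four partitions: `services`, `contexts`, `policies`, `world`.
Identifiers are opaque strings under a single project namespace
(`urn:semflow:`); literals carry a kind tag (string, number, boolean) and
no language tags. Insertion is set-semantic and public growth is
monotone; the only internal deletions are marker rewrites performed by
the offline re-ranking pass (see below).

Serialization goes through rdflib in N-Triples or Turtle. Partition
membership is encoded as comment-delimited sections
(`# semflow-partition: <name>`): comments are legal in both dialects, the
document stays a valid file of the declared dialect, and — unlike tagging
subjects with a membership predicate — the encoding stays lossless even
when the same subject occurs in two partitions, which the randomized
round-trip property exercises. Two further lexical choices keep round
trips exact: floats are written as `repr` under a project datatype
(Turtle writers abbreviate `xsd:double` to numeric tokens with precision
loss), and strings containing control characters are written
unicode-escaped under a second project datatype (strict N-Triples parsers
reject raw control bytes).

## Service registration

A descriptor carries exactly nine parameters: name, description,
framework, dependency list (id, install URI, version), input ports,
output port, category, license, invoke path. Name *legibility* is
interpreted as: non-empty, at most 64 characters, drawn from
`[A-Za-z0-9_-]`, plus system-wide uniqueness. Each service has one
primary input port and exactly one output port, both typed by a frozen
controlled vocabulary of data kinds; the linearity of workflows below is
a direct consequence. Registration is atomic — a rejected record leaves
the space byte-identical. Dependency install URIs are stored, never
executed. Category is free text matched case-insensitively.

## Task contexts and matching

A context is (input kind, domain, desired output kind, dataset
signature), where the signature records row count, column count, ordered
column names, and modality (tabular / counts / text / image). Matching:

* **EXACT** — same task triple (domain compared case-insensitively) and
  same schema. Schema equality deliberately ignores the row count: two
  draws from the same table schema are the same task.
* **TRANSFERABLE** — same task triple, different schema.
* **NONE** — otherwise.

Domain matching is exact string equality (case-folded); fuzzy semantic
similarity of free-text domains is out of scope. Modality inference for
tabular previews uses a heuristic — an all-integer non-negative table
with ≥ 50 columns reads as counts — and can be overridden per request.

## Composition

Services induce a directed multigraph on data kinds (edge = service,
primary input kind → output kind). A workflow is a simple chain (no
repeated service) from the task's input kind to its desired output kind;
`compose` enumerates every such chain up to `max_depth` (default 8) by
depth-first search, with cycles broken by the no-repeat rule. A chain
that reaches the goal kind may legitimately continue through it and reach
it again, so enumeration records and then keeps extending. Completeness
is tested against an independent brute-force oracle that filters all
ordered service subsets.

Ranking is the total order (length ascending, cumulative service reward
descending, lexicographic step-name tuple ascending); cumulative reward
is the sum of each step's lifetime reward from the policy store, in exact
rationals. Single-service solutions are merged into the ranked list ahead
of longer chains automatically, since length leads the sort key.
Preferences pin the service producing a given stage output kind;
candidates without such a stage are unaffected.

## Execution and outcome

Steps run in order via `local:<module>:<function>` invoke paths resolved
to in-process callables; remote URIs are stored but refused at execution.
Execution never raises: a step exception produces a trace with
`succeeded* failed skipped*` statuses and the failing index. One global
seed is threaded to every stochastic service. Success requires all steps
succeeding *and* the chain's final kind equalling the desired output
kind; successful final artifacts are persisted to a content-addressed
directory (JSON manifest + joblib artifact) and can be reloaded and
applied to held-out rows.

## Reward and policy learning

A success with *n* steps rewards each service exactly 1/*n*; a failure
with *m* ≥ 1 surviving steps rewards each survivor 1/*m* (the failure
rule mirrors the success rule at the surviving prefix); *m* = 0 yields an
empty reward list. Rewards are `fractions.Fraction`, so conservation
(success rewards sum to exactly 1) holds without tolerance. Rewards
accumulate additively across records with no decay. The record's
*solution reward* is 1 for success and 0 for failure, optionally replaced
by a clamped [0, 1] human-feedback value whose semantics are
user-defined; it ranks records, while step rewards rank services.

Policy lookup returns records whose stored context matches at EXACT or
TRANSFERABLE level, ordered by (level, solution reward, recency).
Transfer re-executes the best transferable successful workflow on the new
payload — full retraining, zero planner invocations — and writes a new
policy record for the new context. The offline pass (`continuous_update`)
re-derives, per distinct context, a preferred-solution marker =
argmax(solution reward, then recency); it is idempotent. Offline learning
is scoped to this re-ranking; mutating model internals is out of scope.

## World knowledge

Feature-selection facts store (ordered schema, selected subset, source
policy, metric). Reuse fires only on exact ordered column-name equality —
the strictest reading, chosen so that features are never silently reused
across semantically different datasets. When reuse fires, the executor
swaps the optimizer step's callable for a projection-and-refit stage and
flags the trace; the classifier is retrained on the projected columns
(skipping retraining as well would silently trust a stale model). The
projection stage is an executor-level override rather than a registered
service so the planner's candidate set is unaffected. Answer facts and
image-vector facts round trip losslessly; no language or vision model is
shipped, so their service descriptors are registered with callables that
fail cleanly.

## Built-in services

* **Split**: stratified train/test, default ratio 0.8, seeded.
* **Tabular QC**: drop rows with missing values, drop zero-variance
  feature columns.
* **Tabular normalization**: per-feature z-score (idempotent up to
  floating point).
* **Classifier**: standard-scaler + L2-regularized logistic regression
  (C = 1, lbfgs, max 2000 iterations). A linear model keeps the
  elimination criterion below well-defined: importances are absolute
  standardized coefficients.
* **Optimizer**: backward recursive feature elimination — from all *p*
  features, repeatedly drop the feature with the smallest absolute
  standardized coefficient, scoring every subset size with stratified
  k-fold (default k = 5) mean CV accuracy; select the size with maximal
  mean CV accuracy, ties → fewer features; refit on the full train
  partition. This selection rule is written out by hand because library
  RFECV implementations eliminate per fold and select differently.
* **Counts QC**: drop cells with total counts below the q-th percentile
  (default q = 5) and genes detected in < 3 cells. The thresholds are
  common community defaults and are config keys.
* **Counts normalization**: scale each cell to the median total count,
  then log1p.
* **Embeddings**: PCA (full SVD, deterministic up to sign) is the
  always-available built-in; t-SNE (scikit-learn, PCA init) and UMAP
  (umap-learn, optional) register as separate services that fail cleanly
  if unavailable. Default 2 output dimensions.
* **Clustering**: k-means (Lloyd, seeded init, k given, default 3 to
  match the three-population benchmark) and a graph method — kNN graph
  (default 15 neighbours, Euclidean) plus greedy modularity maximization
  (Clauset–Newman–Moore via networkx), with communities labelled by their
  lowest member index for determinism.

Port kinds are stage-distinct for the single-cell path
(`counts_csv_path → count_matrix → qc_count_matrix → normalized_matrix →
embedding → cluster_labels`), so the minimal admissible chain has exactly
the five pipeline stages and the embedding/clustering alternatives are the
only branching points.

## Synthetic study conditions

The generators are pure functions of their spec (seed included) and
return ground truth alongside the data, never inside it.

* **Classification tables**: features are i.i.d. standard normal; the
  label follows a logistic model on the informative subset only, with a
  planted log-odds effect of 1.5 per informative feature, latent logit
  noise sd 0.5, and balanced classes. The benchmark configuration is
  n = 500 rows, 5 informative + 10 noise features. The logistic
  data-generating model matches the linear classifier family, so
  parameter-recovery runs are well-posed.
* **Heart-style table**: exactly the 14 conventional column names
  (age … thal, target) with their categorical encodings; signal is
  planted only in the eight designated features (sex, cp, thalach,
  exang, oldpeak, slope, ca, thal) so selection runs have a known
  answer. This is a schema-faithful synthetic stand-in, not a
  reproduction of any real clinical dataset, and accuracies measured on
  it say nothing about real clinical performance.
* **Parkinson-style table**: a 22-feature voice-measurement schema with
  5 planted informative features; used as the different-schema,
  same-task transfer target.
* **Count matrices**: 300 cells × 400 genes, 3 equal clusters, each
  elevating its own contiguous third of the genes six-fold; per-cell
  totals lognormal around 2000 (sd 0.25, floored at 40% of the mean);
  5% of cells are planted at depths 50–150, far below the 5th depth
  percentile, so the QC cut removes exactly the planted set. Technical
  artifacts of real scRNA-seq (doublets, ambient RNA, batch effects) are
  not simulated, so pipeline recovery here demonstrates the plumbing and
  the planted-structure case, not robustness to real data pathology.

## Problem sizes and numerical choices

Test and acceptance runs use the sizes above (335-row clinical tables,
500-row benchmark tables, 300-cell matrices, 20-seed recovery batches,
100 randomized registries of ≤ 8 services for planner completeness);
these are the package's chosen study conditions. Reward arithmetic is
exact; float comparisons elsewhere use explicit tolerances (z-score
idempotence at 1e-10, PCA against a covariance eigendecomposition at
1e-8 up to sign). Ties are broken deterministically everywhere: triple
matching sorts by (subject, predicate, object), ranking by the sort key
above, elimination drops the first minimal-importance feature,
modularity communities are ordered by lowest node index.

## Known limitations

Workflows are linear chains — no fan-in, no multimodal fusion. Domain
matching is exact, so contexts with synonymous free-text domains do not
transfer. The knowledge store is a single in-memory space serialized to
one file; there is no locking or remote triple store. "Success" means
completion with the correct output kind — no metric threshold is imposed,
the metric is stored for ranking instead. The two descriptor-only model
services (text generation, image classification) execute only as clean
failures.
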