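# Methods

## Model and assumptions

The pipeline targets the setting where a biological contrast (two phenotype
classes) is driven by the coordinated differential expression of genes that
interact, so that the signal lives in small connected subnetworks rather
than in isolated markers. It assumes: (i) exactly two phenotype classes,
each with at least two samples; (ii) an undirected interaction network over
HGNC symbols that covers the genes of interest (edge direction, sign and
weight are ignored); (iii) expression values that are meaningful to rank
within a sample — absolute scale and between-sample calibration are
deliberately not relied on.

## Fuzzy rank normalization

Within each sample of G genes, with n1 = round(θ₁/100·G) and
n2 = round(θ₂/100·G) (round half up), the gene at descending-expression
rank r receives

    v(r) = 1                                  for r ≤ n1
    v(r) = ((G − n2 + 1) − r) / ((G − n2 + 1) − n1)   for n1 < r ≤ G − n2
    v(r) = 0                                  for r > G − n2

The ramp is the unique linear interpolation that meets 1 at rank n1 and 0
at rank G − n2 + 1, so exactly n1 genes sit on the upper plateau and n2 on
the lower one, and the middle stays strictly inside (0, 1). Ties all
receive the mean of the outputs their positions would take under a stable
sort, which makes the transform well defined and permutation invariant.
For very small samples n1 or n2 can round to 0; this is permitted and
logged. Defaults θ₁ = 5, θ₂ = 15.

The legacy alternative (`quantile_z`) quantile-normalizes samples (each
sample's sorted values replaced by the across-sample mean of sorted values,
stable order within a sample) and then z-transforms each gene across
samples using the population standard deviation; zero-variance genes become
all-zero rows.

## Differential expression statistics

The default representative statistic is the two-sided Welch unequal-variance
t-test computed on normalized values, with Welch–Satterthwaite degrees of
freedom. The robust variant (`iqr_t`) replaces each group's sample variance
with (IQR/1.349)², the normal-consistent robust scale, in the same formula;
it reproduces the Welch statistic on clean Gaussian data while damping the
influence of outliers. When both groups have zero spread the statistic
degenerates: equal means give t = 0, p = 1; unequal means give p = 0 with a
logged warning. The fold difference is the difference of mean normalized
expressions (class 1 − class 2); its sign is the regulation direction
reported in graph exports.

## MIS decomposition

The notion of "tightly connected" splitting is realized as greedy
modularity community detection over each connected component, with the
component rebuilt in lexicographic node order so tie-breaking is
deterministic. Communities above `max_size` are re-split recursively; when
modularity refuses to cut a dense blob, a seeded Kernighan–Lin bisection
supplies a deterministic split. Communities below `min_size` are merged
into the neighbor sharing the most edges (ties to the lexicographically
smallest). MISs are disjoint by construction; overlapping subnetworks are
never merged. Defaults `min_size` 5 (so five representatives stay
meaningful) and `max_size` 50 (subnetworks stay much smaller than whole
pathways). Components smaller than `min_size` are skipped with a log
message. The rule is isolated behind `network.decompose` so an alternative
topological splitter can be swapped in. MIS identifiers are a SHA-1 digest
of the sorted gene list, hence stable across folds and runs.

PageRank uses the standard recurrence on the undirected graph (damping
0.85, tolerance 1e-10, max 200 iterations), delegated to networkx; tests
check it against a direct linear solve of the PageRank system.

## Entropy scoring

Samples are embedded as vectors of the (≤ 5) representatives' normalized
expressions and split into k = 2 clusters — one per phenotype context — by
2-means with seeded k-means++ initialization (the randomized farthest-point
scheme) and 10 restarts, keeping the best within-cluster sum of squares.
A degenerate single-cluster outcome (possible only with duplicated points)
is retried with shifted seeds and finally falls back to a midpoint split on
the first representative. The score is the cluster-size-weighted Shannon
entropy of class labels in bits, which is 0 exactly when every cluster is
class-pure and bounded by 1 for two classes. Ranking is ascending by
entropy with ties broken by larger mean |t| of the representatives, then
mis_id.

## Cross-validated consistency

Folds are stratified (per-fold class counts within one of proportionality)
rather than fully random: with tens of samples, unstratified folds can
strip a training set of one class entirely. The fold count is reduced to
the smallest class size when necessary, with a warning. Normalization runs
once before CV; because the fuzzy transform is per-sample, held-out samples
contribute nothing to the training-fold values, so there is no leakage.
Every MIS is scored in every fold (only top-list membership is
fold-limited), so the tie-breaking entropy is the mean over all folds. The
per-fold top-list length K defaults to the number of MISs requested as
output (default 10).

## Stitching

Phase 1 adds every reference-network edge whose endpoints lie in two
different selected MISs. Phase 2 walks MIS pairs in lexicographic id order
and, for each pair still in different connected components of the working
graph, collects all shortest reference paths of at most `max_path_len`
edges (hard bound 4) between cross-MIS gene pairs. Candidate paths are
ordered lexicographically by (edge count, −mean |fold difference| of
intermediate nodes, −mean PageRank over all path nodes, node sequence) —
the fold criterion uses intermediates only because endpoint genes already
belong to MISs — and the top `paths_per_pair` (default 3) are added, their
intermediate nodes marked as bridge nodes. Handling components rather than
ordered pairs means each disconnected pair is bridged once; pairs with no
qualifying path stay disconnected and are logged. A gene's fold difference
is taken from its smallest-p probeset. The full ordering makes the output
byte-stable across runs.

## Synthetic data generator

`synthdata.generate` emulates a two-class expression study over a modular
network: 6 modules of 10 genes (each a spanning cycle plus Erdős–Rényi
edges at p = 0.8, dense enough that any reasonable splitter keeps modules
intact), joined in a ring by 2 random cross edges per adjacent pair; gene
baselines ~ N(8, 1); 2 probes per gene, each observation adding
N(0, σ = 1) noise; 20 + 20 samples; and one planted module whose genes all
shift by δ (default 2σ) in class-2 samples. These defaults represent a
modest, clearly powered microarray contrast; δ and σ are configurable and a
mixed-direction flag flips half the planted genes downward. The generator
does not model background correction, saturation, probe-affinity effects,
or RNA-seq count noise — so passing tests demonstrate the machinery
recovers a coordinated shift under idealized Gaussian noise, not
performance on raw platform artifacts.

## Numerical choices and degenerate inputs

- Plateau counts round half up; the choice is arbitrary but fixed and
  tested.
- Entropy is measured in bits so the two-class score is bounded by 1.
- KMeans, StratifiedKFold and the decomposition all derive their randomness
  from the single run seed (per-MIS seeds add a CRC32 offset of the MIS id
  so cluster restarts differ across MISs but not across runs).
- Missing (NA) expression cells are rejected at parse time rather than
  imputed: a rank-based transform has no principled value for them.
- Probesets mapping to multiple genes are rejected at CHIP parse time
  (conflicting duplicate rows raise an error naming the probe); truly
  multi-gene probes are out of scope.
- Graph exports carry symbol, fold difference, direction and edge
  provenance; SIF, being attribute-free, uses the provenance as its
  relation token.

## Problem sizes

Simulation-based tests and the stability suites run at the generator's
default conditions (60 genes, 120 probesets, 40 samples, 10-fold CV) with
20 seeds per condition and effect sizes δ ∈ {0, 0.5σ, 1σ, 2σ}; path-oracle
checks use 50 random 30-node graphs. These sizes are the package's chosen
test conditions; all thresholds (e.g., 18/20 recovery at 2σ) refer to them.

## Known limitations

- The decomposition is one reasonable reading of "tightly connected"
  splitting; different community methods yield different MIS boundaries,
  which is why the splitter is module-isolated and the CV frequency is the
  primary robustness device.
- Two-phenotype contrasts only; multi-class entropy is not implemented.
- The entropy score compares MISs of similar size fairly, but very small
  MISs with few mapped probesets can score well by chance; the CV frequency
  column is the guard against over-reading them.
- Stitching is greedy per component pair, not a global Steiner-tree
  optimum.
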