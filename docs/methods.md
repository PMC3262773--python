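# Methods

## Model and assumptions

The analysis treats gene regulation as a directed graph over three node
types: transcription factors (TFs), miRNAs, and non-TF protein-coding genes.
An edge TF→x means transcriptional regulation of x; an edge miRNA→x means
post-transcriptional repression of x. Gene nodes are regulatory sinks (no
outgoing edges); TFs and miRNAs may regulate any node type. A *regulation
step* is one edge; the *k-step target set* of a miRNA is every node
reachable from it by a directed path of length ≤ k, excluding the miRNA
itself. By default intermediate regulators count as targets (they are
regulated nodes); a `genes_only` switch restricts the counted universe to
non-TF genes for sensitivity analysis, while traversal still passes through
regulators either way.

Genomic clusters are called by transitive chaining: on each chromosome,
consecutive precursors whose gap (next start − previous end on the sorted
chromosome, clamped at 0 for overlaps) is at most the cutoff belong to one
cluster. Gap-based distance was chosen over start-to-start distance because
it is the usual reading for tandem gene clusters and is insensitive to
precursor length; the cutoff default of 10 kb reflects the valley of the
bimodal inter-miRNA distance distribution, and a `cutoff_scan` utility
reports stability around it. An optional maximum genomic span splits chains
greedily left to right (the short-transcript constraint on intergenic
clusters); greedy splitting was chosen because no canonical split rule
exists and greedy is deterministic and order-free. Strand is ignored by
default (clusters are defined purely by proximity); `same_strand_only` is
available. Coordinates are 0-based half-open internally; GFF3 is converted
on read, BED passes through.

## Statistics

**Normalized composition entropy.** Both the family entropy of a cluster
(E_fam) and the cluster entropy of a module (E_c) are
−(1/ln N) Σ p_i ln p_i over the label composition. For N = 1 the normalizer
1/ln N is undefined; the value is defined as the limit 0 ("all from one
family/cluster") and the code never evaluates ln 1. Tiny floating
excursions are clamped into [0, 1].

**Target overlap.** TO = shared / (min(l_i, l_j) + 1). The +1 keeps the
ratio defined at l = 0 and bounds TO strictly below 1; equal sets of size l
give exactly l/(l+1). Histograms over [0, 1] use right-closed bins (TO = 0
falls in the first bin) so that a tail statement like "TO > 0.8" is exactly
the sum of the last two of the default ten bins.

**MCODE.** Canonical Bader–Hogue on the simple undirected projection of the
directed network (one undirected edge per regulating pair; self-loops
dropped; loops excluded from the density formula 2E/(n(n−1))). Every
parameter is exposed with the canonical defaults (degree cutoff 2, node
score cutoff 0.2, 2-core filter, haircut on, fluff off, max depth 100). All
ties — seed order, neighbor order, output order — break lexicographically,
so output is deterministic. The directed→undirected projection precedes
detection because MCODE is defined on undirected graphs.

**Permutation tests.** Empirical p = (1 + #{null beats-or-ties observed}) /
(1 + B): positively biased, never zero. Three null models:

* *Random clusters*: miRNA ids permuted uniformly into the observed
  cluster-size multiset, isolated miRNAs as size-1 pseudo-clusters.
* *Module membership*: each module's miRNA slot count refilled by drawing
  without replacement from the network's miRNAs; draws are disjoint across
  modules within a replicate (one global permutation sliced into slots). An
  `allow_reuse` flag provides the alternative reading in which modules draw
  independently.
* *TO contrast*: label permutation of the pooled pair TO values between two
  categories; the statistic is the difference of category means. Random-
  category values are pooled over the random cluster sets, which is
  equivalent to averaging per-set statistics because every set has the same
  size multiset.

No multiple-testing correction is applied; raw empirical p-values are
reported. Enrichment uses the *average per-module count* of category
miRNAs (not the total), matching the per-module reading of the statistic.

## Synthetic scenarios

The generator emulates, at desk scale, the statistical structure the
analysis assumes:

* **Layout**: loci (clusters and isolated singletons) are placed round-robin
  over chromosomes with intra-cluster gaps of 2 kb and inter-locus gaps of
  50 kb, so cluster calling at 10 kb recovers the planted clusters exactly,
  by construction, for every valid configuration.
* **Homo-clusters** (default six, sizes 2–4): each member draws
  round(0.9 × 10) = 9 targets from a cluster-specific pool of 10 plus one
  private target. The analytic mean direct TO is (m²/P)/(m+p+1) ≈ 0.736 —
  hypergeometric expected sharing over the pool.
* **Hetero-clusters** (default eight, sizes 2–4): members have disjoint
  direct targets (three private genes) and private TF chains of length
  (convergence step − 1) converging on five cluster-shared terminal genes,
  so pairwise TO is exactly 0 below the convergence step (default 3) and
  positive from it on. Background edges never touch chain TFs (enforced by
  exclusion), so convergence cannot be short-circuited.
* **Modules**: near-cliques of five module TFs plus the attached cluster's
  miRNAs, with all module edges oriented TF→miRNA so module membership
  never contaminates target sets. Five TFs guarantee that every member's
  MCODE weight lies within the default 20% score window of the seed's, so
  detection recovers planted modules exactly; planted modules contain no
  sink genes because gene–gene edges cannot exist and genes dilute
  neighborhood density below that window.
* **Proportions**: 100 miRNAs, 40% clustered (60 isolated) — isolated
  miRNAs in the majority, as in real annotations; ten planted modules, one
  cluster each, leaving some clusters moduleless.
* **null_mode** relabels the network's miRNA nodes by one uniform
  permutation after construction. Degrees are preserved exactly; the
  association between genomic position and network wiring is destroyed.
  Because relabeling is a graph isomorphism, planted-module ground truth
  remains valid (with relabeled members) and the three tests' observed
  statistics become exchangeable with their permutation nulls.

What the generator does **not** emulate: scale-free degree structure,
overlapping or nested modules, expression dynamics, family-driven sequence
similarity, or genome-scale annotation sizes. Passing tests demonstrate that
the statistics recover planted effects under the generator's assumptions,
not that real networks exhibit those effects.

## Numerical and design choices

* **Problem sizes.** The planted-recovery checks run at the default
  100-miRNA scenario with B = 1000 permutation replicates. The p-value
  uniformity checks run on a dedicated `null_calibration_config`: 1200
  miRNAs, 125 clusters of six, 40 ground-truth modules of 12 miRNA slots,
  with 199 permutations per replicate and 200 replicates. The sizes follow
  a granularity analysis, not tuning: a KS comparison against the
  continuous uniform is only valid when the test statistic takes many
  values. The enrichment statistic is a count whose largest null atom is
  ≈ 0.4/sd, so its null sd must exceed ~7 (hence 480 slots from 1200);
  the entropy statistic must not sit on an atom at "all clusters distinct",
  so same-cluster collisions must be near-certain (hence clusters of six
  and a 62% clustered fraction); the TO contrast needs non-degenerate TO
  values, so the calibration preset gives every miRNA four background
  targets (`extra_random_targets`, default 0 elsewhere) and a denser TF web.
  Uniformity replicates evaluate the tests on the ground-truth module
  memberships (valid because relabeling is an isomorphism) to keep 200
  replicates affordable; planted-significance checks use actual MCODE
  detection.
* **Determinism.** Every randomized operation takes an explicit integer
  seed; the pipeline expands one global seed into per-stage substreams via
  `SeedSequence`, so changing one stage's replicate count does not shift
  another's draws. Generator output files are byte-identical per seed.
* **Degenerate inputs.** Empty gene lists cluster to an empty result; a
  module with no clustered miRNAs has undefined E_c and is excluded (error
  if no module qualifies); zero-target miRNAs keep a defined TO through the
  +1; empirical p-values can never be 0.
* **Id namespaces.** Annotation and network ids are matched directly, via
  an optional two-column mapping file, or by a default normalizer that
  strips mature-arm suffixes (-5p/-3p) and case-folds "miR"→"mir".

## Known limitations

* The pair-label permutation contrast assumes exchangeable pair units;
  within-cluster pairs share miRNAs, so for large clusters the test is
  approximate (the uniformity analysis quantifies this only at the
  calibration composition).
* The enrichment and entropy statistics are discrete; with few modules the
  tie-counting p estimator is conservative.
* MCODE parameters strongly shape module size; results should be read
  jointly with the exposed parameter set, and the planted-module guarantees
  hold for the generator's module geometry, not arbitrary dense subgraphs.
* Network construction (TF-binding-site scanning, target prediction) is out
  of scope: the network is consumed as an input file and its quality bounds
  every downstream statement.
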