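# Methods

## Problem

Soil and litter metabarcoding surveys produce OTU-by-sample read count
tables (here: three markers — a bacterial 16S, a eukaryotic 18S and a COI
run — over plot-based samples from four Amazonian habitat types).  The
question is which pairs of taxa co-occur or exclude each other more than
chance would allow, and what the structure of the resulting interaction
network looks like.  Read counts are compositional, noisy, and come from
runs of different depth, so naive correlation thresholds produce large
numbers of spurious edges; the pipeline therefore calibrates every
threshold against explicit null models.

## Preprocessing

Each marker table is handled separately before merging, because the runs
differ in depth:

1. **Depth normalization.**  The expected depth of a run is one half of the
   median per-sample total read count (`depth_factor`, default 0.5).  Every
   sample column is rescaled so its sum equals that depth.  All-zero
   columns cannot be rescaled and are flagged.
2. **Low-abundance filter.**  OTUs whose total (post-normalization)
   abundance does not exceed `filter_fraction` (default 0.10) times the
   median per-OTU total are discarded; this removes singletons and
   near-singletons whose ranks are pure noise.  The median in the rule is
   read as the median of per-OTU totals; the per-sample reading is served
   by the depth step, and both knobs are configurable.
3. **Assembly.**  Surviving OTU rows of all markers are stacked into one
   matrix over the shared sample set (kept in sample-frame order), and one
   row per soil variable (pH, organic carbon, P, exchangeable bases and
   derived indices, Al, texture, …) is appended.  Environmental rows are
   never normalized or noise-injected; they enter the analysis through
   ranks only.  Litter and soil samples are independent columns; there is
   no plot-level pooling.

## Network inference

Association strength is the Spearman rank correlation between rows
(mid-ranks for ties; constant rows give NaN and can never form edges).
Each of `n_monte_carlo` (default 100) Monte-Carlo iterations draws from its
own RNG stream (PCG64, keyed by seed and iteration; samples are put in a
canonical order first, so column order cannot affect the result) and runs
three steps:

1. **Noise injection.**  Uniform noise on `[0, noise_scale)` (default 1.0)
   is added to every OTU entry.  At realistic depths this breaks rank ties
   among equal counts without reordering clearly distinct counts, so each
   iteration sees a slightly different rank configuration; edges that
   depend on tie-breaking or razor-thin margins do not survive the
   consensus step.
2. **Permutation bound.**  Every row of the noise-added matrix is permuted
   independently `n_perm` (default 30) times.  Permutation preserves each
   row's marginal distribution while destroying inter-row dependence.  The
   pooled permuted correlations set the lower bounds for the thresholds:
   in the default `separate` mode the positive bound is the
   `perm_quantile` (default 0.999) quantile of the pooled signed values and
   the negative bound the mirrored lower-tail quantile (this reproduces the
   slightly asymmetric positive/negative thresholds such data produce);
   `symmetric` mode uses the |rho| quantile for both.
3. **Threshold sweep against graph nulls.**  Starting at the bounds, both
   signed thresholds are raised on a common grid (`candidate_step`,
   default 0.01).  At each candidate the combined signed graph (edges with
   rho ≥ t_pos or rho ≤ −t_neg, restricted to non-isolated nodes) is
   accepted if its global transitivity strictly exceeds the
   `graph_null_quantile` (default 0.95) of transitivity in **three** null
   ensembles:

   * the *permutation graphs*: the already-computed permuted matrices
     thresholded at the same candidate.  This ensemble is essential: the
     tail of a sample correlation matrix is triangle-enriched even for
     fully independent data, because two chance correlations sharing a row
     make the closing correlation stochastically large.  Density- or
     degree-matched random graphs do not reproduce that geometry, so
     without this ensemble the test accepts thresholds on pure noise.
   * `n_graph_null` (default 100) *Erdős–Rényi* graphs matched on the
     observed average degree, and
   * 100 *Chung–Lu* graphs matched on the observed degree sequence
     (edge (i,j) with probability min(1, d_i d_j / Σd)).

   The smallest accepted candidate defines the iteration's thresholds and
   signed edge set.  Iterations accepting no candidate contribute an empty
   edge set.  Acceptance is evaluated on the combined graph, not per sign,
   because co-exclusion subgraphs are nearly bipartite and triangle-free
   (their transitivity is structurally ~0), so a per-sign clustering test
   could never admit negative edges.

The **consensus network** keeps every signed pair present in at least
`consensus_fraction` (default 0.90) of the iterations; edge support is the
containing fraction and the edge weight the mean rho over containing
iterations.  Reported thresholds are the means of the accepted
per-iteration thresholds.  Isolated nodes are dropped; nodes carry kind
(otu/env), taxonomy, trait and total-abundance annotations.

Behavior on the two canonical regimes (both recomputed by
`scripts/acceptance.py` and the test suite):

* independent multinomial tables (500 OTUs × 40 samples): 0 consensus
  edges per replicate;
* planted-module tables (ten 8-OTU modules at loading 0.9, four exclusion
  pairs, 80 samples): precision ≳ 0.94 and recall ≳ 0.95 on ground-truth
  positive pairs, all exclusion pairs recovered as negative edges.

## Graph properties

Computed per scope (whole signed graph, co-occurrence subgraph,
co-exclusion subgraph), treating each scope as a simple unsigned graph:
maximum component (ties broken by smallest sorted node-id set), diameter
and average path length on the maximum component, global transitivity,
modularity Q under the connected-component partition, LC modularity
(Q under a seeded Louvain partition; a within-community averaged variant is
available behind a flag), nominal assortativity per categorical attribute,
per-node degree, and key nodes.  "High betweenness" for key nodes is
unquantified in common usage; the rule here is articulation points whose
unnormalized betweenness reaches the 75th percentile over all nodes
(configurable).  Every metric is cross-checked in the test suite against a
brute-force implementation (flood fill, all-pairs BFS, exhaustive triple
enumeration, direct formula evaluation) on seeded random graphs.

## Ecology layer

Habitat breadth uses raw (pre-normalization) occurrence: an OTU recorded
in exactly one habitat is a *specialist*, in three or more a *generalist*;
the residual two-habitat class is labeled *intermediate* so the three
labels partition all observed OTUs.  Per-habitat (and per-habitat-within-
locality) networks re-run the entire preprocess+infer pipeline on the
subset's samples and the OTUs recorded in them, re-deriving thresholds per
subset; subsets with fewer than 3 samples are skipped.

## Synthetic communities

The generator emulates the survey design: localities × habitats × plots ×
two substrates, with a plot-level soil chemistry draw (habitat-specific
baselines; SB, t, T, V, m derived from the base cations, so the usual
pedological collinearity is present) shared by the two substrate samples.

Abundances follow a latent Gaussian factor model, chosen because Spearman
correlation detects any monotone dependence and loadings then map directly
to effect size: log-abundance of OTU i of module k in sample s is
`mu_i + loading * f_ks + eps`, with `f_ks ~ N(0,1)` shared by the module,
`mu_i ~ N(0, 1)` (between-OTU spread) and `eps ~ N(0, 0.5)` (within-OTU
noise).  Exclusion pairs load on a shared factor with opposite signs.
Background OTUs are independent with total variance matched to planted
rows.  Environmental links add `alpha * f_ks` (scaled by the variable's
own spread) to a soil variable.  Counts are multinomial per sample at a
log-normal depth (CV 0.3), so the compositional closure of real amplicon
data is present; no log-ratio correction is applied, matching the
pipeline's rank-based analysis.  A `rare_fraction` of background OTUs is
masked to one or two plots, reproducing the empirical pattern that most
OTUs occupy fewer than five plots (at the study preset's 0.6 the median
occupancy is below five plots).

Two presets fix the study conditions:

* `study_spec()` — the full emulation: 39 plots × 2 substrates = 78
  samples (terra-firme and igapó in all four localities, campina in three,
  várzea in two — the only allocation consistent with the per-locality
  habitat availability and 39 plots), three markers at depths
  50k/30k/20k, 200 background OTUs per marker, ten 8-OTU modules, four
  exclusion pairs, environmental links to organic carbon (positive) and
  base saturation (negative), rare fraction 0.6.
* `benchmark_spec()` — the recovery benchmark: one marker, 80 samples
  (4 localities × 2 habitats × 5 plots × 2 substrates), ten 8-OTU modules
  at loading 0.9, four exclusion pairs, 120 background OTUs, rare fraction
  0.25.  The background size is desk-scale by design: it keeps a full
  inference run in seconds while leaving enough independent pairs
  (~20,000) for the false-positive side of precision to be meaningful.

What the generator does **not** emulate: sequence-level artifacts (chimeras,
PCR bias, clustering errors), phylogenetic signal in abundances, spatial
autocorrelation between plots, and non-monotone associations.  Passing the
planted-recovery benchmark therefore shows the inference chain is correct
and calibrated for monotone latent-factor associations under multinomial
sampling — not that field data meet those assumptions.

## Numerical choices and edge cases

* Spearman via mid-ranks + matrix product, clipped to [−1, 1]; constant
  rows are NaN against everything and cannot form edges.
* ER and Chung–Lu realizations are exact independent Bernoulli draws over
  the upper-triangle pair list; the public graph constructors and the
  internal ensembles share this core.
* Consensus weights are rounded to 6 significant digits and supports to 3
  decimals when the edge record is created, so file output is byte-stable
  and write→read round-trips are exact.
* Degenerate inputs: all-zero samples are left unscaled (flagged); an
  empty filter result returns an empty table with a warning; modularity
  and assortativity of edgeless or single-label graphs are NaN with a
  warning; empty scopes report zero/NaN rows.
* FDR/benchmark problem sizes used by the tests and the acceptance script
  (500×40 nulls at 25 Monte-Carlo iterations ×10 replicates; 80-sample
  benchmarks at the default 100 iterations × 5 seeds) were chosen so a
  full validation runs on one CPU in a few minutes.
* `generate_null` defaults to 10,000 reads/sample in the validation runs:
  a realistic amplicon depth for 500 OTUs that leaves many per-cell counts
  of order 1–100, which is the regime the uniform noise injection is
  designed for (it must be able to perturb ranks of borderline pairs).

## Known limitations

* Rank correlation on compositional data still carries closure-induced
  negative bias; the pipeline mirrors the published practice of not
  applying a log-ratio transform, and the null calibration absorbs most
  but not all of it (spurious negative edges are the dominant error mode
  in the benchmark).
* The permutation-graph ensemble uses `n_perm` replicates (default 30), so
  its transitivity quantile is coarse; raising `n_perm` sharpens the test
  at linear cost.
* Very small subsets (< ~10 samples) yield permutation bounds near 1 and
  usually empty networks — the method has no power there, matching the
  caveat that applies to the smallest habitat subsets in real surveys.
* Thresholds are reported as means over accepted iterations; an edge kept
  by consensus is guaranteed to beat each containing iteration's own
  threshold, not the reported mean, so edge weights can sit up to about
  one grid step below `t_pos` (or above `t_neg`).
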