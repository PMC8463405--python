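# coexnet

Null-model-calibrated **co-occurrence / co-exclusion network inference**
for soil and litter metabarcoding data, with the full graph-property suite
used to compare microbial community networks across habitats, and a
synthetic community generator with planted ground truth so the entire
pipeline can be validated end to end.

The package targets plot-based multi-marker OTU surveys (for example
16S/18S/COI runs over Amazonian terra-firme, campina, várzea and igapó
plots, with litter and mineral-soil samples per plot and per-plot soil
physicochemistry), but any OTU-by-sample count tables plus a sample
metadata table will do.

## Method in brief

Association between two rows (OTU or soil variable) is the Spearman rank
correlation ρ across samples.  An edge requires ρ to clear a threshold
that is calibrated, per Monte-Carlo iteration, by two classes of null
models:

1. **Matrix nulls** — uniform noise on [0, 1) is added to every OTU entry,
   and each row of the noise-added matrix is independently permuted 30
   times; the 0.999 tail of the pooled permuted ρ distribution sets the
   lower bound for the threshold (per sign, so the positive and negative
   thresholds come out slightly asymmetric).
2. **Graph nulls** — the candidate threshold is raised in 0.01 steps until
   the thresholded graph's global transitivity exceeds the 95% quantile of
   transitivity in the permuted-matrix graphs at the same threshold and in
   Erdős–Rényi (average-degree-matched) and Chung–Lu
   (degree-sequence-matched) random graph ensembles.

The **consensus network** keeps every signed pair present in ≥ 90% of 100
such iterations; positive edges form the co-occurrence network, negative
edges the co-exclusion network.  On independent data this yields empty
networks; on data with latent shared factors it recovers the planted
structure with high precision (see below).

Downstream, the package computes maximum component, diameter, average
path length, transitivity, modularity (component partition), LC modularity
(seeded Louvain partition), nominal assortativity by taxonomic group,
degrees, and key nodes (articulation points with top-quartile betweenness
— candidate keystone taxa); classifies habitat generalists (≥ 3 habitats)
and specialists (exactly 1); and builds per-habitat and
per-habitat-per-locality networks with subset-specific thresholds.

## Worked example

```python
from coexnet import benchmark_spec, generate, NullModelConfig, run_pipeline
from coexnet.graphprops import report, metrics_table

data = generate(benchmark_spec(seed=1))          # 80 samples, 10 planted modules
net = run_pipeline(data.tables, data.frame, NullModelConfig(seed=1),
                   env_vars=[], taxonomy=data.taxonomy, traits=data.traits)
print(f"edges: {len(net.edges)}  nodes: {len(net.nodes)}")
print(f"thresholds: t_pos={net.thresholds.t_pos:.3f}  t_neg={net.thresholds.t_neg:.3f}")
pos = {(e.node_a, e.node_b) for e in net.edges if e.sign == "pos"}
tp = len(pos & data.truth.positive_pairs)
print(f"precision={tp/len(pos):.3f}  recall={tp/len(data.truth.positive_pairs):.3f}")
print(metrics_table(report(net, seed=1)).round(3))
```

prints

```
edges: 295  nodes: 107
thresholds: t_pos=0.342  t_neg=-0.342
precision=0.957  recall=0.950
                        all  co_occurrence  co_exclusion
n_nodes             107.000         95.000        27.000
n_edges             295.000        278.000        17.000
max_component_size   17.000          9.000         4.000
diameter              4.000          2.000         3.000
avg_path_length       1.926          1.194         1.667
transitivity          0.926          0.979         0.000
modularity            0.875          0.901         0.886
lc_modularity         0.934          0.901         0.886
n_key_nodes           7.000          4.000         7.000
```

The 80-sample benchmark plants ten 8-OTU modules (factor loading 0.9) and
four exclusion pairs among 120 background OTUs.  The accepted Spearman
thresholds settle near ±0.34; of the 278 positive consensus edges, 95.7%
are planted module pairs, and 95% of all planted pairs are recovered
(precision/recall above are computed against the generator's ground
truth).  Co-occurrence transitivity is high because modules are cliques;
co-exclusion transitivity is 0 because exclusion structure is two-sided
(bipartite, hence triangle-free) — the same signature reported for real
soil networks.  Modularity ≈ 0.9 reflects ten nearly disconnected
modules.

The same pipeline is available from the shell:

```sh
coexnet simulate --preset benchmark --seed 1 --outdir run/inputs
coexnet preprocess --counts run/inputs/counts_16S.tsv \
        --samples run/inputs/samples.tsv --env-vars "" --out run/matrix.tsv
coexnet infer --matrix run/matrix.tsv --seed 1 --outdir run/network
coexnet metrics --network run/network --out run/metrics.json
coexnet all --config config.yaml        # one-shot run with manifest.json
```

## Layout

```
src/coexnet/
  io.py          TSV / GraphML readers and writers, domain types
  simulate.py    synthetic communities with planted ground truth
  preprocess.py  depth normalization, abundance filter, matrix assembly
  nullmodel.py   Spearman + permutation/graph nulls + consensus network
  graphprops.py  network property suite (components ... key nodes)
  ecology.py     habitat breadth, per-habitat networks, composition tables
  cli.py         click CLI (simulate/preprocess/infer/metrics/classify/
                 habitats/all) with reproducibility manifest
tests/           pytest suite incl. brute-force oracles and end-to-end checks
docs/methods.md  model, assumptions, parameter choices, limitations
```
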