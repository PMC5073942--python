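# netmark

Topology-aware discovery of **subnetwork markers** for phenotype
classification on protein–protein interaction (PPI) networks.

Single-gene expression signatures for outcomes such as cancer metastasis
reproduce poorly across cohorts. A more robust alternative aggregates genes
whose protein products sit close together in a PPI network into *subnetwork
markers* and uses each subnetwork's summarized activity as one classification
feature. `netmark` implements an affinity-propagation approach to this
problem: genes are clustered with a message-passing algorithm over a
similarity that fuses **discriminative power** with **network topology**, the
resulting subnetworks are ranked by the discriminative power of their
activity, and the top-ranked ones become the marker panel.

## Method

For gene *i* with expression *x<sub>i</sub>* and per-phenotype Gaussian
densities *f¹*, *f²*, the log-likelihood ratio (LLR) is

> λ(x<sub>i</sub>) = log [ f¹(x<sub>i</sub>) / f²(x<sub>i</sub>) ]

Let t<sub>i</sub> be the two-sample t statistic of gene *i*'s LLR profile
between phenotypes and t<sub>ik</sub> that of the summed profiles of genes
*i*, *k*. The discriminative-power similarity (with penalty weight α ∈ [0,1])
is the directed score

> s<sub>DP</sub>(i,k) = t<sub>k</sub> + min{t<sub>ik</sub>−t<sub>i</sub>, t<sub>ik</sub>−t<sub>k</sub>} − α·|t<sub>i</sub>−t<sub>k</sub>|

Topological similarity s<sub>T</sub>(i,k) is a neighborhood-overlap index of
the interaction-partner sets N<sub>i</sub>, N<sub>k</sub>: Jaccard
(|N<sub>i</sub>∩N<sub>k</sub>| / |N<sub>i</sub>∪N<sub>k</sub>|), Kulczyński
(the average of the two common-neighbor proportions), or the asymmetric
Tversky index with weights (1, 0), which reduces to
|N<sub>i</sub>∩N<sub>k</sub>| / |N<sub>i</sub>|. The two scores are fused
either as a product, s = s<sub>T</sub>·s<sub>DP</sub>, or as a convex
combination s = β·s<sub>T</sub> + (1−β)·ŝ<sub>DP</sub> of s<sub>T</sub> with
the min–max rescaled s<sub>DP</sub>. Affinity propagation then partitions the
genes, with every self-similarity set to a common preference *c* chosen so
that only 1 % of directed pair similarities fall at or below it. Each
cluster's activity A(𝒢) = Σ<sub>i∈𝒢</sub> λ(x<sub>i</sub>) is scored by its
|t| between phenotypes, and the top *K* (default 50) clusters form the
marker set, evaluated by LDA classifiers under repeated stratified
cross-validation (AUC).

The six method variants are named `jac_p`, `kul_p`, `tve_p` (product) and
`jac_lc`, `kul_lc`, `tve_lc` (linear combination).

## Worked example

Generate a synthetic benchmark (planted-partition network, 300 genes in 30
modules of 10; 3 "disease" modules whose genes carry a 1.5 σ class-mean
shift; 50 samples per phenotype), discover markers with the Tversky/product
variant, and inspect the result:

```bash
netmark simulate --out sim --seed 3
netmark discover \
    --expression sim/expression.tsv --labels sim/labels.tsv \
    --network sim/network.tsv --mapping sim/mapping.tsv \
    --preset tve_p --seed 3 --out run
netmark stats --markers run/markers.json
```

prints `50 markers -> run/markers.json` and then

```json
{
  "dp_curve": {
    "10": 11.91567263249863,
    "20": 8.14400241833312,
    "30": 6.640774129958621,
    "40": 5.677585148877778,
    "50": 4.898869060586765
  },
  "mean_marker_size": 5.9,
  "n_markers": 50,
  "unique_gene_count": 295
}
```

`dp_curve` is the mean |t| of the top-K markers' activity — the three
planted disease modules dominate the head of the ranking (the top marker
reaches |t| ≈ 21.6 on this seed, against a background of |t| ≈ 1), and the curve
decays toward the noise level as K grows. `markers.json` carries each
marker's member genes, exemplar, activity t score and the full run
configuration; `markers.gmt` is the same panel as a standard gene-set file.
Evaluate a panel on another dataset (activities recomputed there, LLR
parameters re-fit per training fold) with `netmark evaluate`.

The library mirrors the CLI one-to-one, e.g.:

```python
from netmark.pipeline import RunConfig, run_discover
from netmark.synthetic import SyntheticSpec, generate_dataset

net, truth, expr, mapping = generate_dataset(SyntheticSpec(seed=3))
result = run_discover(expr, net, mapping, RunConfig.preset("tve_p", seed=3))
print(result.markers.markers[0])
```

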