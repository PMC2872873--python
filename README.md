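# modsubnet

Modular subnetwork biomarkers of aging: discovery of connected gene sets on a
weighted functional interaction network whose aggregate expression tracks
chronological age, permutation-based significance testing, support-vector
age prediction, and gene-set enrichment.

## The problem

Single-gene biomarkers of aging are noisy and poorly conserved between
studies. A subnetwork biomarker replaces one gene by a connected set of genes
on an interaction network, summarized by its *activity* — the mean normalized
expression of its members per sample. This package scores a candidate
subnetwork N by

```
S = R + β·M
R = |Spearman(a, c)|             # activity vs. age: class relevance
M = W_in / (W_in + W_out)²       # weighted local modularity
```

where `a` is the activity vector, `c` the sample ages, `W_in` the
member-internal edge weight counted once per endpoint and `W_out` the weight
of boundary edges (so the denominator is the total strength of the member
nodes). Edges are weighted by the absolute Spearman correlation of their
flanking genes' expression. The coefficient β trades data-driven relevance
against prior network structure; β = 0 recovers purely relevance-driven
("regular") subnetwork scoring.

Subnetworks are grown greedily from every seed gene (adding at each step the
neighbor that most increases S without decreasing R or M), tested for
significance with a self-contained (age-permutation) and a competitive
(artificial-interactome) test, reduced to a non-redundant set (Jaccard >
0.25 rule), and used as regression features or annotated by hypergeometric
gene-set enrichment. A latent-factor synthetic-data generator with planted,
age-responsive modules makes the whole pipeline testable without external
data.

## Worked example

```python
import modsubnet as ms

spec = ms.SyntheticSpec(rng_seed=7)   # 5 planted age-modules, 300 background genes
g, membership = ms.generate_network(spec)
d = ms.generate_expression(spec, g, membership)
gw = ms.weight_network(g, d)

beta = ms.calibrate_beta(gw, d, rng_seed=7)
print(f"calibrated beta = {beta:.1f}")

sub = ms.grow_subnetwork("mod01_g01", gw, d, mode="modular", beta=beta)
print(f"seed mod01_g01 grew to {sub.size} genes: {', '.join(sub.members)}")
print(f"R = {sub.relevance:.3f}, M = {sub.modularity:.4f}, S = {sub.score:.3f}")

p = ms.self_contained_test(gw, d, beta=beta, n_perm=99, rng_seed=7)
print(f"self-contained p for this seed: {p['mod01_g01']:.3f}")
```

prints

```
calibrated beta = 2.9
seed mod01_g01 grew to 5 genes: mod01_g01, mod01_g06, mod01_g03, mod01_g04, mod01_g08
R = 0.944, M = 0.0214, S = 1.007
self-contained p for this seed: 0.010
```

The seed sat inside a planted module; greedy growth collected four of its
co-members, the aggregate activity correlates with age at ρ = 0.944, and the
score beats all 99 age-permutation null searches from the same seed
(add-one p = 1/100).

`calibrate_beta` returns the ratio median(R)/median(M) over random connected
subsets — the β at which the two score terms carry comparable weight.

### sklearn integration

```python
from modsubnet import SubnetworkDiscovery, make_age_pipeline

pipe = make_age_pipeline(network=g, beta=250.0, max_features=25)
pipe.fit(X_train, age_train)       # X: samples × genes
age_pred = pipe.predict(X_test)
```

`SubnetworkDiscovery` is a standard transformer (`fit`/`transform`/
`get_params`), so it composes with sklearn pipelines and model selection.

### Command line

```sh
modsubnet simulate --out-dir study/ --seed 7
modsubnet grow --network study/network.tsv --expr study/expression.tsv \
               --meta study/metadata.tsv --mode modular --beta 250 --out subs.tsv
modsubnet test --network study/network.tsv --expr study/expression.tsv \
               --meta study/metadata.tsv --n-perm 1000 --n-interactomes 100 \
               --seed 17 --out significance.tsv
```

See `modsubnet --help` for `predict`, `cv` and `enrich`.

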