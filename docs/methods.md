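# Methods

## The model

The package identifies *subnetwork biomarkers* of aging: connected gene sets
on a functional interaction network whose aggregate expression tracks
chronological age. A candidate subnetwork N with normalized member expression
rows z_1..z_n has

* **activity** a = mean(z_1..z_n) per sample,
* **class relevance** R = |Spearman(a, c)| against the sample ages c,
* **modularity** M = W_in / (W_in + W_out)^2, a weighted local community
  fitness: W_in sums the member-internal edge weights once per endpoint (each
  internal edge contributes 2w), W_out sums the weights of boundary edges, so
  the denominator is exactly the total strength of the member nodes,
* **score** S = R + β·M.

Edge weights are the absolute Spearman correlation of the two flanking genes'
expression, so weights, R and S are invariant under any monotone per-gene
transform. β trades data-driven relevance against prior network structure;
β = 0 recovers purely relevance-driven ("regular") subnetwork scoring.

## Greedy search

One subnetwork is grown per seed gene. At each step every network neighbor of
the current member set is evaluated:

* **modular mode** — a candidate must not decrease R, must not decrease M
  (constraint applied only when β > 0, so that β = 0 is exactly a
  pure-relevance greedy), and must strictly increase S; the qualifying
  candidate with the largest S is added. Growth halts when no neighbor
  qualifies.
* **regular mode** — candidates are restricted to nodes within graph distance
  2 of the seed (computed once); the candidate with the largest relevance gain
  is added provided the per-step gain is at least r. The threshold r is
  interpreted per step (ΔR ≥ r), which reproduces the observed behavior that
  larger r yields smaller subnetworks; a cumulative-threshold reading is the
  noted alternative.

Numerical comparisons use a tolerance SCORE_EPS = 1e-9: rank statistics take
discrete values with gaps far above it, so smaller differences are float
noise from re-deriving the same quantity along two routes. Ties within
SCORE_EPS break toward the lexicographically smallest gene id, which makes
every search deterministic and serial/threaded runs bit-identical.

Redundancy removal processes subnetworks in descending score order and keeps
one iff its Jaccard overlap with every kept set is ≤ 0.25 (strictly-more-than
eliminations, per the stated rule). The elimination order is not prescribed
by the source protocol; descending score greedily maximizes retained score.

## Significance

Two permutation schemes, both with add-one empirical p-values
p = (1 + #{null ≥ true}) / (1 + n) so p is never 0 and significance at
α = 0.001 under 1,000 permutations means rank 1:

* **self-contained** — ages are shuffled jointly over all samples and the
  all-seed search re-run; each seed is ranked against its own permutation
  scores. Ties count against significance (≥, conservative).
* **competitive** — gene labels are shuffled over network positions
  ("artificial interactomes"), edge weights recomputed from the new flanking
  genes, the search re-run, and every true score ranked against the pooled
  scores of all artificial subnetworks.

Defaults match the reference protocol (1,000 permutations at α = 0.001; 100
interactomes at α = 0.05). The desk-scale test suite uses reduced counts
(40–200 permutations, 8–15 interactomes, α = 0.05) chosen so the smallest
attainable add-one p still clears the threshold; these are flagged where
used.

## Prediction

Subnetwork (or single-gene) activities feed an ε-insensitive support vector
regression with linear kernel and conventional defaults (C = 1, ε = 0.1),
pinned in code for reproducibility. Features are not re-standardized before
the SVR (activities are already means of z-scores). Performance is MSE and
SCC (squared Pearson between true and predicted age); SCC is offset-invariant,
which matters when cohorts differ in lifespan. Feature-sampling experiments
draw k ∈ {5, 10, 25, 50} features without replacement (canonical sorted order
within a draw), 1,000 draws by default, and summarize each metric by its
median with a 2,000-resample percentile-bootstrap 95% CI. Cross-validation
uses age-stratified folds (each age group dealt round-robin from a rotating
offset, so per-fold counts within an age group differ by ≤ 1) and repeats
discovery, selection and training inside each training fold; a deliberately
leaky variant (`discover_on="all"`) exists purely as a contrast demonstrating
why per-fold discovery is required. The gene baseline ranks genes by one-way
F-test across age groups with Benjamini–Hochberg adjustment.

## Enrichment

Over-representation uses the upper-tail hypergeometric test against the
analyzable network universe (never the whole genome), BH-adjusted across the
sets tested, with an optional coverage filter (a category must annotate at
least 25% of the query's genes in the annotation-transfer workflow). The
GO-graph "elim" decorrelation of the original GO analysis is out of scope;
plain per-term hypergeometric + BH is used for all collections. Cross-study
conservation is the Jaccard percentage of significant seed sets with an
upper-tail hypergeometric p for the intersection.

## Synthetic data

The generator realizes the structure the score assumes. A network of planted
modules (internal edge probability 0.9 by default) sits in an Erdős–Rényi
background (probability 0.02), attached by 2 bridge edges per module;
remaining components are joined so the graph is always connected. Optionally,
sparse cross-module edges (`cross_module_edge_prob`) embed the modules in a
patchwork-of-communities topology resembling a real interactome. Expression:
each module has a latent activity slope·age + N(0,1), standardized to unit
variance; member genes load it with coefficients drawn from (0.4, 0.8) (sign
shared within a module) plus N(0, gene_noise_sd²) gene noise; background
genes are standard normal. The latent is standardized so loadings and noise
share a scale — without this, any slope ≥ 1 puts every single gene at the
relevance ceiling and greedy growth has nothing to gain from aggregation.
Optionally every gene also receives a weak independent age slope drawn from
N(0, individual_slope_sd²), emulating the diffuse transcriptional drift of
aging outside the coherent modules. Defaults (5 modules × 10 genes, 300
background genes, slope 1.0, noise 0.5, 10 samples at each of 5 ages) give a
regime where single genes correlate with age at |ρ| ≈ 0.6–0.8 and module
activity approaches the latent's own age correlation (~0.95).

The β calibration utility reports median(R)/median(M) over random connected
subsets — the ratio at which β·M and R are comparable in magnitude, the
"equal importance" operating point.

What the generator does **not** emulate: platform/batch effects, probe-level
noise, dye bias, scale-free topology, and — critically — the strength regime
of a real interactome. Real functional networks have node strengths of
~15–40, where M ≈ 0.004 and the fitness W_in/T² is maximized by whole
modules. Desk-scale networks with co-expression weights (null |ρ| ≈ n^{-1/2})
cannot exceed strengths of a few, where tight two-gene sets can attain
M ≈ 0.2–1.0. Consequences, documented here because they shape the tests:

* module recovery is non-monotone at very low gene noise — aggregate
  relevance saturates immediately and the ΔR ≥ 0 rule stalls growth — so the
  monotonicity check uses noise levels 0.5 / 2.0 / 4.0, all at or above the
  saturation knee;
* the competitive test loses power when β is large, because the
  topology-preserving null inherits the M-rich positions; the cross-study
  comparison therefore runs at 0.25× the calibrated ratio, within the span of
  the reference presets (whose smallest is 0.5× its own ratio);
* desk-scale feature pools are ranked by the self-contained test (which
  eliminates age-irrelevant high-M candidates) rather than the double filter,
  which cannot pass enough non-redundant subnetworks at these sizes.

Passing tests therefore demonstrate the machinery's correctness and the
direction of every headline comparison at desk scale, not the magnitudes
reported for real microarray cohorts.

## Degenerate inputs and conventions

Constant activity ⇒ R = 0 with a warning (a flat subnetwork carries no
signal); isolated member sets ⇒ M = 0; singletons ⇒ M = 0 and are never
reported as significant (minimum reported size 2); constant predictions ⇒
SCC = 0 with a warning; component ties in `restrict_to_universe` break toward
the component containing the lexicographically smallest gene; missing values
are imputed by the gene's median over non-missing samples after the 30%
per-age-group filter (strict inequality); normalization is a per-gene z-score
(population variance). Imputation and normalization are this package's
choices — the source protocol states neither.

## Problem sizes in the test suite

The acceptance-style tests run: oracle equivalence on 1,000 random instances
per primitive; the M bound on 10,000 random subsets; the β = 0 reduction on
100 instances; module recovery on 20 replicates × 3 noise levels (350-gene
networks); null calibration on 10 replicates of 100 genes at 200
permutations; conservation on 10 replicate study pairs (160-gene patchworks,
60 permutations, 12 interactomes); prediction comparisons on 100 draws and 20
CV replicates. These sizes keep the full suite within a half hour on one core
while leaving every comparison's Monte-Carlo error well below the asserted
margins.
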