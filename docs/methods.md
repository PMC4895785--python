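# Methods

## Scope and model

metasig implements a stage-stratified drug-repositioning analysis for
paired tumor/normal expression cohorts. Its unit of evidence is the
*drug connectivity record*: for one drug in one cohort, an enrichment
score ES ∈ [−1, 1] (negative when the drug-induced expression profile
anti-correlates with the disease signature) and a p-value. The pipeline's
claim structure is: genes that change reproducibly (paired testing →
cross-cohort agreement), filtered to network/annotation-supported key
genes by two independent routes, define the signature; drugs whose records
reverse that signature consistently across cohorts — judged by
meta-analysis rather than any single cohort — are repositioning
candidates.

## Paired differential expression

Genes are tested on per-pair tumor − normal log2 differences with a
paired t-test (df = n_pairs − 1), two-sided, BH-adjusted across genes;
default α = 0.05 on the adjusted p. Inputs are assumed log2-normalized
upstream. Optional moderation replaces each gene's difference variance s²
by 0.5·s̄² + 0.5·s² (s̄² the across-gene mean), a fixed-prior-weight
shrinkage that stands in for empirical-Bayes moderation; degrees of
freedom are left unchanged. Zero-variance genes with nonzero mean are
reported at the machine p-floor (1e−300) with ±∞ t and a warning; with
zero mean they are never called. The exported query signature floors the
*linear* fold-change magnitude at 5.64 (a connectivity-map search
convention); the floor never feeds back into testing or any downstream
statistic.

## Consensus classification (route A)

Features, computed over the full PPI + annotation tables:

- **CLD** — count (and fraction) of a gene's PPI partners labelled cancer.
- **DFS** — mean over the gene's domains d of c_d/(c_d + n_d), where
  c_d/n_d count labelled cancer/non-cancer proteins carrying d (0 when
  unobserved). Aggregation by mean is the default; `max` is available.
  The choice matters little for ranking-driven selection and was fixed
  once.
- **DDI propensity** — the gene's domain-pair types (d, d′) with its
  neighbors' domains; the fraction of those types observed on at least one
  cancer/cancer interacting protein pair. Pair *types* (not instances) are
  counted, and "cancer pair type" means some carrier edge joins two
  cancer-labelled proteins; both readings of an ambiguous definition were
  fixed once and documented here.

Genes lacking PPI membership or domain annotation are excluded from
candidacy; unknown-label genes are scored but never trained on. Training
down-samples the majority class to equal counts (seeded); metrics (hit
ratio, F1, AUC) come from 10-fold stratified cross-validation on the
balanced set. The five families — decision tree, depth-1 stump (one-rule),
distance-weighted kNN (locally weighted), random forest, L2 logistic
regression — are deliberate stand-ins for one classifier per family of the
original toolkit-bound design; the pipeline's logic (three features +
strict 5/5 voting + cross-dataset intersection) is the preserved
contribution, not any specific learner.

## Topological classification (route B)

The up- (down-) regulated network is the PPI subgraph induced by the
cross-dataset common DEGs plus their first neighbors. Eight metrics per
node, oriented so larger = more central: degree; unnormalized shortest-path
betweenness; bridging centrality = betweenness × bridging coefficient
BC(v) = (1/deg v)/Σ_{u∈N(v)} (1/deg u); harmonic closeness Σ 1/d(v,u)
(chosen because these subgraphs are often disconnected; classic closeness
is a config alternative); eccentricity centrality 1/ecc(v) within the
node's component; local clustering coefficient; brokering coefficient
(1 − CC(v))·deg(v)/(n − 1); local average connectivity (mean degree of
N(v) in the subgraph induced by N(v)). Isolated nodes take 0 for all
distance-based metrics.

Selection: per parameter, the top ⌈top_frac·|pool|⌉ DEGs (default
top_frac = 0.2; boundary ties all included — reproducible across
platforms) score one point; the ranking pool is DEG-only by default
(neighbors shape metric values but are not ranked; a full-network pool is
a config option). Group winners: the default `full` rule takes DEGs that
score in *every* parameter of a group. This is the one genuinely open
design point: the alternative `max` rule (attainers of the maximum
observed positive score) reads more naturally but is provably not
monotone in top_frac — widening the quantile can create a higher observed
score in a two-parameter group and silently drop previous winners — which
contradicts the selection's intended nesting (top 10% ⊆ 20% ⊆ 30%). The
`full` rule coincides with `max` on single-parameter groups 1–3 and is
monotone on all groups; `max` is retained as an option for comparison.

## Over-representation analysis

One-sided hypergeometric tail P(X ≥ overlap) with population |universe|,
successes |set ∩ universe|, draws |query|; sets with p < 0.05 ranked
ascending, BH-adjusted p reported over all tested sets. The universe
defaults to all genes measured in the expression studies (the natural
sampling frame for a query drawn from them); web-service enrichment tools
this replaces do not disclose their universe, so it is configurable.

## Drug meta-analysis and screening

Per drug with records (ES_i, p_i, n_i), i = 1..k:

- Fisher pooling: F = −2 Σ ln p_i, referred to χ²(2k).
- Effect sizes: Y_i = arctanh(ES_i), V_i = 1/(n_i − 3) (ES treated as a
  correlation; |ES| = 1 clipped to 1 − 1e−6 with a warning), weights
  W_i = 1/V_i; M = ΣW_iY_i/ΣW_i, V_M = (ΣW_i)⁻¹, 95% CI M ± 1.96·SE_M.
- Heterogeneity: Cochran's Q = ΣW_i(Y_i − M)² with *squared* deviations
  (the unsquared form can be negative and makes I² ill-defined),
  df = k − 1, I² = max(0, (Q − df)/Q)·100. If the χ²(df) upper-tail p of
  Q is ≥ 0.1 the fixed-effect model is kept; otherwise DerSimonian–Laird
  τ² = max(0, (Q − df)/(ΣW − ΣW²/ΣW)) re-weights with 1/(V_i + τ²).
  k = 1 gives Q = 0, df = 0, I² = 0, fixed model by convention.
- Z statistics: unweighted Z = M_u/SE_u with unit weights; weighted
  Z = ΣW_iY_i/√(ΣW_i²). The weighted form is kept exactly as defined in
  the source method — it is the unique form that reduces to the unweighted
  Z when all V_i are equal, a property the tests pin down — even though
  the conventional meta-analytic Z divides by √(ΣW_i); it is conservative
  relative to that convention. The one-tailed p_MA is the lower normal
  tail of the weighted Z (efficacy is encoded as ES < 0).

Screening conditions (ml route): A/B filter records to ES < 0 and
per-dataset p < 0.1 / < 0.5, require survivors in ≥ min_datasets
(default 2) datasets, meta-analyze survivors, keep p_MA < 0.05; C/D
meta-analyze all ES < 0 records and keep p_MA < 0.05 / < 0.1. The ml drug
set is the union of A–D. The topology route keeps drugs with ES < 0 and
p < 0.05 in ≥ min_datasets datasets. "ES < 0" is evaluated per record
(surviving-record semantics): a drug needs no negative record in *every*
dataset, only in the records that enter the meta-analysis. The
≥ min_datasets gate for A/B, and p_MA < 0.05 as the post-meta retention
rule, are documented choices where the source procedure is underspecified;
both are config values. Set overlaps are reported as Jaccard indices
JI = |A∩B|/(|A|+|B|−|A∩B|).

## Target mapping

Targets of the screened common drugs are retained iff they are key genes,
ranked by distinct-drug count (ties: lexicographic). Non-target PPI nodes
adjacent to ≥ 1 retained target are ranked by adjacent-target count;
the top 3 distinct counts are reported. Nodes that are themselves targets
are excluded from this ranking, because its purpose is to find connector
hubs that are neither key genes nor targets.

## Synthetic world

Defaults state the verification conditions: 4 datasets × 20 tumor/normal
pairs × 2000 genes; 10% of genes planted as DEGs at |log2FC| = 2 (half up,
half down, the same set for every dataset of a stage); measurement noise
sd 0.3 (log2); per-dataset batch shift sd 0.2 added to planted effects —
the heterogeneity the Q/I² machinery must detect; 10% cancer-labelled
genes grown over PPI neighborhoods with domain assignments biased toward a
small cancer-domain pool (so CLD/DFS/DDI are informative); 500 drugs, 4%
effective with reversal sets seeded from 80% of the planted signature;
ES = −overlap/|signature| + shift_d + N(0, 0.05), clipped to [−1, 1], with
the per-dataset ES shift drawn at sd = batch_sd/2 (half the expression
batch sd, keeping shifts small against the unit ES range). Permutation
p-values use B = 200 label permutations with the add-one estimator
(b+1)/(B+1), so p > 0 always (Fisher's method diverges at p = 0); the
permutation null is sampled through the exactly equivalent hypergeometric
overlap draw for speed, with the same noise and dataset shift applied so
null p-values are calibrated. The PPI is preferential-attachment (m = 3)
with one planted hub — a non-DEG gene wired to every planted DEG of both
stages and padded until it strictly dominates all degrees.

What the generator does **not** emulate: probe-level microarray structure,
normalization artifacts, correlated noise between genes, realistic
pathway topology in the GMT sets, or drug records whose ES derives from an
actual rank-based connectivity statistic. A green recovery test therefore
establishes that the pipeline's logic recovers planted structure under its
own model assumptions — not performance on real cohort data.

## Numerical choices and degenerate inputs

- p-values floored at 1e−300; BH adjustment via the standard step-up.
- ES = ±1 clipped to ±(1 − 1e−6) before arctanh, logged.
- Boundary ties in every ranking are all included; remaining ties break
  lexicographically.
- Empty intersections (key genes, pathways, drugs) are valid results with
  warnings, not errors; an empty regulated network (no DEG in the PPI) is
  an error.
- Determinism: every stochastic step derives its generator from the run
  seed plus a fixed per-module stream tag; identical config + seed gives
  bit-identical artifacts.

## Known limitations

- The DEG stage substitutes a plain paired t-test (optional fixed-weight
  shrinkage) for full empirical-Bayes moderation after RMA; inputs must
  arrive normalized.
- Connectivity records are consumed as data; the rank-based enrichment
  statistic behind real connectivity scores is not reimplemented.
- Classifier families are fixed stand-ins; no hyperparameter search or
  calibration is attempted, and reported CV metrics describe the balanced
  training sample only.
- With few targets or tiny networks, rank-1 hub recovery can tie between
  several nodes; ranks are reported with ties rather than broken
  arbitrarily.
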