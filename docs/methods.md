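# Methods

`cavenet` implements the downstream statistical pipeline of an amplicon
survey of microbial communities — as practiced in cave/soil microbiome
studies of methanotrophs (pmoA OTUs) and whole bacterial communities (16S
ASVs) — from a count table to diversity indices, environment–community
association tests, a signed co-occurrence network, and Zi–Pi keystone-taxon
classification.  A synthetic community generator with planted ground truth
makes every stage testable without sequencing data.

## Tables

The root object is a features × samples matrix of non-negative integer
counts.  Three transformations precede analysis:

* **Rarefaction** draws, per sample, a multivariate hypergeometric
  subsample (without replacement) at a common depth, so library-size
  differences do not masquerade as diversity or correlation differences.
  The depth is a required choice; the drivers use 8,000 reads, just below
  the smallest simulated library.  Rarefaction is seeded and
  bit-reproducible.
* **Relative abundance** divides each sample column by its total.
* **Prevalence/abundance filter** retains features whose *mean* relative
  abundance across samples exceeds 0.1% and which are present in more than
  20% of samples.  Both thresholds are strict inequalities, and the
  abundance criterion uses the mean (the common convention; a per-sample
  maximum criterion would be an alternative reading).  Both are
  configurable.  Whether the filter is better applied before or after
  rarefaction is debatable; the pipeline applies it after, so the filter
  sees the same library size the network sees.

## Diversity

* **Chao1** (bias-corrected): `S_obs + F1(F1−1)/(2(F2+1))` with `F1`/`F2`
  the singleton/doubleton counts; reduces to observed richness without
  singletons.
* **Shannon** `H = −Σ p_i ln p_i` over non-zero proportions, natural log by
  default (configurable base).
* **Kruskal–Wallis** (tie-corrected, chi-square approximation) for group
  differences in alpha diversity.  Fully tied input carries no evidence
  against the null and returns `H = 0, p = 1` rather than NaN.
* **Bray–Curtis** `d(u,v) = 1 − 2·Σ min(u_i,v_i)/(Σu_i + Σv_i)`.
* **PCoA** by classical (Torgerson) scaling.  Bray–Curtis is not Euclidean,
  so negative eigenvalues occur; they are dropped and explained variance is
  reported over positive eigenvalues only, so the percentages sum to 100.
* **UPGMA** (average linkage).  Dendrogram heights are *half* the
  between-cluster average distance (molecular-clock convention), so the
  leaf-to-leaf path through the tree equals the cophenetic distance; the
  newick export carries branch lengths under this convention.

## Environment–community association

Environmental distance is Euclidean on z-standardized variables (units are
incommensurable: pH vs mg·kg⁻¹ vs ppm); a constant variable contributes
zero distance.  The **Mantel test** correlates the upper triangles of the
community and environmental distance matrices (Spearman by default,
Pearson selectable) and obtains significance from simultaneous row/column
permutations of one matrix: one-sided, `p = (#{r_perm ≥ r_obs}+1)/(B+1)`,
with `B = 9,999` by default.  The permutation engine is seeded; the null
calibration (uniform p under independence) is asserted in the test suite.
The variable-wise correlation screen reports rho, p, and the conventional
star classes (`*` 0.01<P<0.05, `**` 0.001<P<0.01, `***` P<0.001);
zero-variance columns yield explicitly undefined cells.

## Co-occurrence network

All unordered pairs of filtered features are scored with tie-aware Spearman
correlation (two-sided p via the t approximation, adequate at n = 36
samples; constant features are excluded and recorded).  P-values are
Benjamini–Hochberg adjusted over all pairs jointly.  An edge is kept iff
`|rho| ≥ 0.7` and `q < 0.05`: the strength threshold is applied to the
absolute value, because observed networks of this kind contain negative
links; the sign is kept as an edge attribute.  Whether the 0.05 cut was
meant for raw or adjusted p is ambiguous in common usage; adjusted is the
default, raw is selectable.  Nodes are edge endpoints only — filtered
features with no surviving correlation do not appear, which is why node
counts fall well below candidate counts.

Topology metrics: density `2E/(N(N−1))`, average degree `2E/N`, average
weighted degree (mean over nodes of Σ|rho| of incident edges), average
clustering coefficient (degree-0/1 nodes contribute 0), average path
length over *connected* pairs and diameter as the largest finite
eccentricity (threshold graphs are routinely disconnected), and the
positive-edge fraction.  Module detection is Louvain-style greedy
modularity maximization on the |rho|-weighted graph with a fixed seed and
size/id tie-breaking, reporting Newman's Q.  Modules holding strictly more
than 5% of nodes are flagged "large".

## Node roles and keystones

On the unweighted graph (plain degree counts, the original
role-cartography definition):

* `Zi` — within-module degree z-score; modules with zero degree variance
  (including singletons) give `Zi = 0`, keeping those nodes peripheral
  unless `Pi` promotes them.
* `Pi` — participation coefficient `1 − Σ_s (k_is/k_i)²`.

Classification uses the standard thresholds — peripheral (`Zi ≤ 2.5`,
`Pi ≤ 0.62`), connector (`Zi ≤ 2.5`, `Pi > 0.62`), module hub (`Zi > 2.5`,
`Pi ≤ 0.62`), network hub (both above) — with keystones = non-peripherals.
Role percentages and keystone shares are reported to two decimals and each
sums to 100.

## Synthetic communities and what they do (and do not) show

Each of `M` planted modules has a latent standard-normal factor per sample.
A member feature's log-abundance signal is `±√r·f_m + √(1−r)·ε`, where
`r = 2·sin(π·ρ/6)` converts the target Spearman ρ into the Gaussian Pearson
correlation; the sign is negative with probability
`negative_assoc_fraction` (default 5%).  Planted connectors load evenly on
3 modules and carry no idiosyncratic noise — even so, their correlation
with any one module's members is capped at `√r/√span ≈ 0.56`, an
arithmetic fact that any detection method inherits.  Log-abundances (a
lognormal baseline, sd 1.2, plus the dispersion-scaled signal) pass
through a softmax to per-sample compositions, and counts are multinomial
draws at a uniformly random depth (default 8,000–12,000 reads).  Default
scale mirrors the motivating study design: 36 samples (3 caves × 2 sites ×
2 niches), ~900 features, 11 modules.

Environmental variables are linear in single module factors plus unit
noise (defaults: pH and CH4 on the dominant module at effect 2.5, CO2 on a
second module at 1.5, Cl⁻ pure noise).  Two compositional effects shaped
the defaults and are worth knowing when interpreting tests:

* **Closure distortion.** Because compositions are closed, a swing in a
  dominant module's factor moves every other feature's relative abundance.
  Strong dominance therefore (i) dampens the dominant module's own
  within-correlations and (ii) induces spurious negative correlations
  elsewhere.  The dominant-module size weight is 1.5 for this reason; at
  that level no closure-induced edge survives the 0.7 threshold, so
  planting no negative associations yields a 100%-positive network.
* **Gradient dilution.** A gradient tied to one of 11 modules can only
  align with a fraction of the community-wide Bray–Curtis variation;
  Mantel r tops out around 0.2–0.4 even for a perfectly measured factor
  (comparable to published per-variable Mantel values in such surveys),
  and a single draw at n = 36 is occasionally non-significant.  Tying one
  variable to several modules does *not* help: distances on a sum of
  factors cancel where community distances add.

The generator emulates over-dispersion, sparsity, compositionality, block
correlation, and environmental coupling; it does not emulate sequencing
error, chimeras, phylogenetic correlation, or spatial autocorrelation
between samples.  Passing recovery tests therefore shows the pipeline's
inferential machinery is sound under its own model, not that real cave
communities satisfy that model.

## Problem sizes and numerical choices

Tests run the generator at reduced scale (60–200 features, 3–8 modules)
with study-size samples (24–36); partition recovery uses a 4-block
strong-signal regime (ρ = 0.95), and connector recovery uses 8 modules,
deep sequencing (4–6 × 10⁴ reads) and a 0.45 edge threshold, pooled over
three replicates — the 1/√3 ceiling puts connector edges below the 0.7 cut
by construction, which the analysis drivers also report.  Mantel null
calibration uses 500 replicates of 199 permutations at n = 10.  All
randomness flows through explicit seeds (`numpy.random.default_rng`);
reruns are byte-identical.  Eigenvalues below `max(1e-12, 1e-10·λ₁)` are
treated as zero in PCoA; BH q-values are clipped at 1; modularity uses
|rho| weights (signed-modularity variants are out of scope).

## Known limitations

Plain Spearman co-occurrence on compositional data is biased (the closure
effects above); compositionality-aware estimators (SparCC, SPIEC-EASI) are
deliberately out of scope because the implemented pipeline mirrors the
plain-correlation practice.  Zi–Pi uses the unweighted graph; weighted
variants are not provided.  PERMANOVA, NMDS, phylogenetic diversity,
random-forest importance ranking, and structural equation modeling are
out of scope.
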