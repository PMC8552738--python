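# cavenet

Diversity and co-occurrence network analysis for microbiome amplicon count
tables, written for studies of cave and soil communities — e.g. atmospheric
methane-oxidizing bacteria (pmoA OTUs) alongside whole bacterial
communities (16S ASVs) sampled from weathered cave rock.

Starting from a features × samples table of non-negative integer counts,
the pipeline computes:

* **Alpha/beta diversity** — bias-corrected Chao1
  (`S_obs + F1(F1−1)/(2(F2+1))`), Shannon `H = −Σ p_i ln p_i`,
  Kruskal–Wallis group tests, Bray–Curtis dissimilarities
  (`1 − 2·Σ min(u,v)/(Σu+Σv)`), classical PCoA, and UPGMA clustering with
  newick export.
* **Environment–community association** — seeded Mantel permutation tests
  (Spearman r of distance-matrix upper triangles, one-sided p from 9,999
  simultaneous row/column permutations) and a variable-wise correlation
  screen with significance stars.
* **Signed co-occurrence network** — all-pairs tie-aware Spearman
  correlation on rarefied counts filtered at >0.1% mean relative abundance
  and >20% occurrence; edges where `|ρ| ≥ 0.7` and Benjamini–Hochberg
  `q < 0.05`, sign kept as an attribute; full topology summary (APL, ACC,
  diameter, modularity, density, average (weighted) degree, positive-edge
  fraction); Louvain module detection; Gephi-loadable edge list and
  GraphML export.
* **Keystone taxa** — within-module connectivity `Zi` and participation
  coefficient `Pi = 1 − Σ_s (k_is/k_i)²` per node, the standard four-way
  role classification (thresholds 2.5 / 0.62), keystone summaries by
  taxonomy, and keystone subnetworks.
* **Synthetic communities** — a seeded generator of compositional,
  over-dispersed count tables with planted correlation modules, connector
  taxa, environmental gradients, and taxonomy, plus recovery scoring
  (adjusted Rand index, edge precision/recall, connector recall) against
  the planted truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (all seeded; outputs under `results/`):

```sh
python analysis/01_simulate.py          # 900 features x 36 samples, 11 planted modules
python analysis/02_diversity.py         # Chao1/Shannon, PCoA, UPGMA
python analysis/03_environment.py       # Mantel tests per variable
python analysis/04_network.py           # Spearman/BH network + topology
python analysis/05_node_roles.py        # Zi-Pi roles and keystones
```

With the default seed, `04_network.py` prints:

```
283/900 features pass the 0.1%/20% filter
 Nodes  Edges   APL   ACC  Diam  Modularity  Density     AD    AWD  PositiveEdgeFraction  Modules
   277   2400 1.619 0.783     5       0.863    0.063 17.329 13.437                 0.976       11
97.58% of edges are positive; 11 modules
planted-partition recovery: ARI = 1.000 over 276 nodes
```

Reading: of 900 simulated features, 283 are abundant and prevalent enough
for network inference; 277 of them retain at least one edge with
`|ρ| ≥ 0.7` and `q < 0.05`. Louvain finds exactly the 11 planted modules
(adjusted Rand index 1.0 against the planted partition), and 97.6% of
edges are positive — the generator plants 5% negative associations, and
compositional sampling keeps a few of them below threshold.  And
`03_environment.py` prints (999 permutations shown; the default is 9,999):

```
              r      p  n_perm stars
all       0.259  0.003     999    **
pH        0.071  0.156     999
CH4_ppm   0.153  0.037     999     *
CO2_ppm   0.266  0.002     999    **
Cl        0.059  0.232     999
```

pH, CH4 and CO2 carry planted gradients; Cl is pure noise. Gradients tied
to single modules dilute in community-wide Bray–Curtis comparisons, so
per-variable r sits in the 0.1–0.3 range typical of such surveys and the
weakest gradient is not always individually significant.

The same pipeline is scriptable via the `cavenet` CLI (`simulate`,
`filter`, `diversity`, `mantel`, `network`, `roles`, `run-all`) or the
library (`cavenet.run_all(AnalysisConfig(...), table, taxonomy,
metadata)`).

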