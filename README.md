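# isolocal

Global conservation prioritisation schemes rank species by how much unique
evolutionary history they carry on the complete phylogeny of their clade —
but conservation is mostly carried out on local communities, which sample
relatively few species from across that tree. `isolocal` asks how well
*global* evolutionary-isolation scores predict the same species'
*local* (within-community) isolation and contribution to community
diversity, and what is lost when globally top-ranked species are removed
from communities.

The package is aimed at conservation phylogeneticists and community
ecologists working with survey data (e.g. route-level bird counts), a
species-pool tree ensemble, and a mixed-type trait database.

## Metrics

For a rooted phylogeny with branch lengths, three species-level isolation
scores are computed at global (species-pool) and local (community sub-tree)
scope:

- **ED** — fair-proportion evolutionary distinctiveness:
  ED(*i*) = Σ<sub>e ∈ path(root, i)</sub> ℓ(e) / n(e), where n(e) is the
  number of tips descending through edge *e*.  ED partitions the tree:
  Σ<sub>i</sub> ED(*i*) equals the total branch length.
- **PE** — the pendant edge (terminal branch length), a species' unique
  contribution to phylogenetic diversity.
- **APD** — average pairwise (patristic) distance,
  APD(*i*) = (n−1)<sup>−1</sup> Σ<sub>j≠i</sub> d(*i*, *j*).

Community diversity is **PD** (Faith's phylogenetic diversity, rooted
convention: the spanning subtree includes the path to the root).  Trait
analogues are built from a Gower mixed-type distance matrix with a
median-imputation rule for species pairs sharing no scored trait:
**TU** (minimum trait distance to any other species in scope) and **TAPD**
(mean trait distance to all others in scope).

The analysis has two arms:

1. **Concordance** — per community, Spearman's ρ between each global score
   (ED, PE, APD) and each local score (ED, PE, APD, TU, TAPD), summarised
   across communities (mean ρ, s.d., share of communities with p < 0.05).
2. **Removal experiment** — the globally top-K species by each metric are
   removed from every community; PD loss and TAPD change are compared with
   removing the same number of species uniformly at random (R replicates),
   with add-one empirical p-values and Benjamini–Hochberg FDR control
   across communities.

Because the original survey, tree and trait databases are external, the
package ships a first-class synthetic generator (`isolocal.simulate`):
Yule pool trees, branch-length-jittered tree ensembles, Brownian/Mk traits
evolved on the tree, and abundance-weighted communities with tunable
phylogenetic clustering.

## Worked example

```bash
isolocal simulate --out demo --n-species 60 --n-trees 3 \
    --n-communities 20 --richness 26 40 --seed 7
isolocal scores --trees demo/trees.nwk --out demo/global_scores.csv
isolocal concordance --trees demo/trees.nwk \
    --communities demo/communities.csv --traits demo/traits.csv \
    --trait-spec demo/trait_types.json --out-dir demo/out
isolocal removal --trees demo/trees.nwk \
    --communities demo/communities.csv --traits demo/traits.csv \
    --trait-spec demo/trait_types.json --k 10 --replicates 200 \
    --seed 7 --out-dir demo/out
```

`demo/out/concordance_summary_FULL.csv` then contains one row per metric
pair, e.g. (run exactly as above):

```
pair,n_communities,mean_rho,sd_rho,prop_significant
ED~local_ED,20,0.7840216746827346,0.09965135222734334,1.0
PE~local_PE,20,0.6525542565941123,0.14245083129851197,1.0
APD~local_APD,20,0.9023375924445336,0.1841703242522686,0.95
...
```

Read: global APD ranks species almost the same way locally as globally
(mean ρ = 0.90 over 20 communities), noticeably tighter than the PE–PE
concordance (mean ρ = 0.65).  `demo/out/removal_summary_FULL.csv` reports,
per ranking metric, the mean observed PD loss against the mean random-null
loss — here 12.6 vs 4.5 tree-length units for APD, i.e. top-ranked
removals lose more than twice as much local PD as random ones — alongside
the mean TAPD change (positive = the depleted community is more
trait-similar) and the share of communities whose PD loss is significant
after FDR control (1.0 for APD at α = 0.05).

The same steps are available as library calls (`simulate_bundle`,
`ScoreTable.from_ensemble`, `concordance_analysis`, `removal_analysis`);
see the module docstrings.

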