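# Methods

This note records the models, conventions and numerical choices behind
`isolocal`, and what the synthetic study system does and does not emulate.

## Isolation metrics and conventions

All phylogenetic metrics operate on rooted trees with non-negative branch
lengths and uniquely labelled tips; zero-length edges and polytomies are
legal throughout (fair proportion needs no special casing for polytomies —
the per-edge tip count simply counts all descendants).

- **ED (fair proportion).** Each edge's length is divided equally among
  the tips descending through it; a tip's ED is the sum of its shares on
  the root-to-tip path.  This makes ED an exact partition of total tree
  length, which the test suite asserts to 1e-9 relative tolerance, and
  implies ED ≥ PE for every tip.
- **APD.** Mean patristic distance to the other n−1 species.  The
  denominator is n−1 (self-distance excluded), the literal reading of
  "mean distance to all *other* species"; a divide-by-n variant is exposed
  via `average_pairwise_apd(..., denominator="n")` but unused by the
  pipeline.
- **PD, rooted convention.** Faith's PD of a species set includes the path
  from the set's MRCA up to the tree root.  This keeps single-lineage
  contributions positive, makes PD(all tips) equal total tree length (and
  hence equal ΣED), and makes the pruned community sub-tree's total length
  equal the community's PD exactly.  An MRCA-rooted variant
  (`rooted=False`) is available but not used by the pipeline.
- **Pruning.** Community sub-trees keep the root path; degree-2 nodes
  created by pruning are suppressed with their edge lengths summed, except
  the root itself (so the rooted-PD identity holds).
- **Ensemble aggregation.** Scores are medians across the replicate trees;
  even ensemble sizes use the arithmetic midpoint.  Ensembles must share
  one identical tip set; sub-species substitution and name dropping happen
  upstream in the community module.

## Trait distances

Quantitative traits are standardised by dividing by the column mean
(computed over non-missing entries) rather than centring, since Gower
range-normalisation expects non-negative comparable scales; a centring
option exists but is off by default.  Gower distances average per-trait
distances over the traits scored for *both* species: range-normalised
absolute differences for quantitative traits, the same on mid-rank scale
for ordinals, 0/1 mismatch for nominals.  Zero-range columns contribute
distance 0 with a warning (the behaviour of the standard `daisy`
implementation).  Only species pairs with *no* shared scored trait receive
the median of all computable pairwise distances, and are flagged in an
imputation mask.

Local (community) TU and TAPD are computed on the principal submatrix of
the global distance matrix — pairwise distances are reused, not
re-range-normalised within the community.  A `renormalize` switch in
`community_trait_matrix` recomputes Gower from scratch on the community's
rows for sensitivity analyses.

## Community filters

Communities are the union of species over all survey years on a route,
with counts summed.  The richness filter (default: keep ≥ 25 species) and
name reconciliation run once on the FULL dataset; the NO_ALIENS and
NO_RARE variants are derived independently from FULL, without re-applying
the richness filter (they are variants of the *same* communities).  The
rare-species rule is strict: a species is removed when its count is
strictly below 1% of the community's total individuals, so a species at
exactly 1% is kept.  All filters are idempotent.

## Statistics

- **Spearman's ρ** uses mid-ranks for ties and the two-sided
  t-approximation p-value, t = ρ√((n−2)/(1−ρ²)) on n−2 d.f.; perfectly
  concordant or discordant rank vectors are detected exactly and return
  ρ = ±1 with p = 0 by convention.  Communities contribute a concordance
  record per metric pair only when ≥ 3 species are shared and neither
  vector is constant; undefined records are carried but excluded from
  summaries.  Species lacking trait data are excluded pairwise from
  trait-based pairs only.
- **Empirical p-values** for the removal experiment use the add-one
  estimator p = (1 + #{null ≥ observed})/(R + 1), one-sided "greater"
  (the question is whether prioritised removal loses *more* than random).
- **FDR** is Benjamini–Hochberg, applied across communities separately
  within each ranking metric and separately for the PD and TAPD tests.
- **Random removals** are uniform over the community's species (not
  abundance-weighted), sampled without replacement, with one child RNG
  stream per community so results are bit-reproducible under a seed and
  independent of community ordering.

The removal experiment's sign convention for TAPD change is
(mean pairwise trait distance before) − (after): positive values mean the
depleted community is more trait-similar, i.e. trait outliers were
removed.  Communities left with fewer than two trait-scored species after
removal contribute PD loss but are excluded from TAPD summaries.

## Synthetic study system

The generator produces a desk-scale analogue of a continental survey
dataset; its defaults are the package's standard study conditions.

- **Pool tree:** pure-birth (Yule) with birth rate 1, 300 species by
  default (depth ≈ ln n).  The tree **ensemble** (default 10 trees) keeps
  the base topology and multiplies each edge by an independent unit-mean
  log-normal factor (σ = 0.1) — a cheap stand-in for a posterior tree set
  that preserves tip sets; the median-based scores are robust to the local
  rearrangements this omits.
- **Traits:** 15 quantitative columns by Brownian motion (variance
  σ²·branch length, σ = 1, started well away from zero so column means
  stay positive for mean-standardisation) and 7 nominal columns by a
  symmetric 10-state Mk process at rate 0.2, with 10% missing cells.
  These defaults mirror the shape of field trait databases for birds:
  a 13-trait table expands to ~22 columns once diet composition is scored
  as ten quantitative columns, and categorical traits such as nest type
  (14 types) or nest substrate (11 types) are many-state and
  phylogenetically conserved — at rate 0.2 a lineage expects < 1 state
  change per root-to-tip path, whereas a fast clock would saturate the
  tree and erase the trait–phylogeny link the analysis studies.
- **Communities** (default 200): richness uniform on [26, 150] — the
  lower bound matching the richness filter's boundary, the upper bound
  keeping desk-scale runtimes (larger ranges are one config field away);
  members are a uniformly chosen seed species plus k−1 species sampled
  with weight exp(−α·patristic distance to the seed).  The default
  clustering is weak (α = 0.1): real route-level bird communities sample
  broadly across the continental tree (waterfowl, raptors, waders,
  passerines), and strong clustering (α ≥ 0.5) collapses communities into
  single clades — a regime in which local APD decouples from global APD
  and which does not resemble the surveyed data.  Abundances are rounded
  log-normals (σ = 1.5), giving realistic rank-abundance curves with a
  share of species under the 1% rare threshold.

What the generator does **not** emulate: spatial structure and
autocorrelation of routes, observation error and effort differences,
topological uncertainty in the tree ensemble, taxonomic mismatch beyond a
user-supplied synonym map, and correlated trait evolution.  Passing tests
therefore demonstrate the pipeline's correctness and the qualitative
behaviour of the metrics under idealised assembly assumptions — not
quantitative agreement with any particular empirical dataset.

## Problem sizes and determinism

The test suite and the reproduction script run the full analysis at the
default scale above (300-species pool, 200 communities, top-30 removal,
200-replicate nulls, 20 replicate studies for the directional checks) —
sizes chosen so a complete run finishes in minutes on a single core while
keeping Monte-Carlo standard errors well inside the margins being tested.
Every stochastic component draws from `numpy.random.default_rng` streams
spawned from a single seed, so all outputs are bit-reproducible.

## Known limitations

- Newick/NEXUS parsing is delegated to dendropy; extremely large tree
  files are read eagerly into memory.
- The patristic matrix is dense O(n²); pools beyond ~10⁴ species would
  need a different APD strategy.
- The concordance arm recomputes local scores by pruning every tree in
  the ensemble for every community; for very large ensembles, pass a
  subsampled ensemble (the scores are medians and stabilise quickly).
- The spatial regression of concordance on geography/habitat covariates
  reported alongside this style of analysis is out of scope, as is map
  rendering and fuzzy taxonomic matching.
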