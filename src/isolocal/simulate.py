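"""Synthetic trees, trait tables and communities for end-to-end runs.

The generator emulates the statistical structure the analysis assumes:

* a pure-birth (Yule) species pool phylogeny, plus an ensemble of replicate
  trees obtained by jittering branch lengths (a stand-in for a posterior
  tree set — same topology, log-normally perturbed edges);
* quantitative traits evolved by Brownian motion and nominal traits by a
  k-state Markov (Mk) process along the tree, so trait distance is
  positively correlated with patristic distance; cells are masked missing
  at a configurable rate;
* communities that are abundance-weighted subsets of the pool with tunable
  phylogenetic clustering: a uniformly chosen seed species plus members
  sampled with weight exp(-alpha * patristic distance to the seed)
  (alpha = 0 gives uniform subsets), with log-normal abundances so that a
  share of species falls under rare-species thresholds.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .communities import CommunityTable
from .errors import ConfigError
from .traits import NOMINAL, QUANTITATIVE, TraitTypeSpec
from .trees import Node, PhyloTree, TreeEnsemble, patristic_matrix, write_trees


@dataclass
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults give a desk-scale analogue of a continental survey dataset:
    a 300-species pool, a 10-tree ensemble, 200 communities with richness
    drawn uniformly from [26, 150] and weak phylogenetic clustering, and a
    mixed trait table shaped like a field trait database — 15 Brownian
    quantitative columns (think body mass, clutch size, ten diet
    components, habitat/diet breadths) and 7 slowly evolving nominal
    columns with 10 states (nest type, substrate, guild...), with 10%
    missingness.
    """

    n_species: int = 300
    n_trees: int = 10
    birth_rate: float = 1.0
    jitter_sd: float = 0.1
    n_communities: int = 200
    richness_range: tuple[int, int] = (26, 150)
    clustering_alpha: float = 0.1
    abundance_sigma: float = 1.5
    n_quant_traits: int = 15
    brownian_sigma: float = 1.0
    n_nominal_traits: int = 7
    mk_rate: float = 0.2
    n_states: int = 10
    missingness: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        lo, hi = self.richness_range
        if self.n_species < 2:
            raise ConfigError("n_species must be >= 2")
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        if self.birth_rate <= 0:
            raise ConfigError("birth_rate must be > 0")
        if lo < 2 or hi < lo:
            raise ConfigError("richness_range must satisfy 2 <= lo <= hi")
        if not 0.0 <= self.missingness < 1.0:
            raise ConfigError("missingness must be in [0, 1)")
        for name in ("jitter_sd", "clustering_alpha", "abundance_sigma",
                     "brownian_sigma", "mk_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_states < 2:
            raise ConfigError("n_states must be >= 2")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _tip_label(i: int) -> str:
    return f"sp{i + 1:04d}"


def simulate_yule_tree(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> PhyloTree:
    """Pure-birth (Yule) tree with ``cfg.n_species`` tips.

    Exponential waiting times between speciations (rate = lineages x
    birth_rate); after the last split, lineages are extended by one more
    exponential waiting time, so the tree is ultrametric.  Tips are
    labelled sp0001... in preorder.
    """
    if rng is None:
        rng = cfg.rng()
    lam = cfg.birth_rate
    root = Node()
    active: list[tuple[Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < cfg.n_species:
        t += rng.exponential(1.0 / (len(active) * lam))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.length = t - birth if node is not root else 0.0
        node.children = [Node(), Node()]
        active.extend((c, t) for c in node.children)
    t += rng.exponential(1.0 / (len(active) * lam))
    for node, birth in active:
        node.length = t - birth
    tree = PhyloTree(root, validate=False)
    for i, tip in enumerate(tree.tips):
        tip.label = _tip_label(i)
    tree._validate()
    return tree


def simulate_tree_ensemble(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> TreeEnsemble:
    """A base Yule tree plus ``n_trees - 1`` branch-length-jittered variants.

    Each variant multiplies every edge length by an independent log-normal
    factor with unit mean (sigma = ``jitter_sd``); topology and tip set are
    identical across the ensemble.
    """
    if rng is None:
        rng = cfg.rng()
    base = simulate_yule_tree(cfg, rng)
    trees = [base]
    mu = -0.5 * cfg.jitter_sd**2  # unit-mean multiplier
    for _ in range(cfg.n_trees - 1):
        variant = base.copy()
        if cfg.jitter_sd > 0:
            for node in variant.preorder():
                node.length *= float(rng.lognormal(mu, cfg.jitter_sd))
        trees.append(variant)
    return TreeEnsemble(trees)


def make_trait_spec(cfg: SimConfig) -> TraitTypeSpec:
    """The type declaration matching :func:`simulate_traits` output."""
    kinds: dict[str, str] = {}
    for i in range(cfg.n_quant_traits):
        kinds[f"quant_{i + 1}"] = QUANTITATIVE
    for i in range(cfg.n_nominal_traits):
        kinds[f"nominal_{i + 1}"] = NOMINAL
    return TraitTypeSpec(kinds)


def simulate_traits(
    tree: PhyloTree, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Traits evolved on the tree; rows are tip labels.

    Quantitative traits follow Brownian motion (variance sigma^2 x branch
    length) from a positive root value well away from zero, so column means
    stay positive for mean-standardisation.  Nominal traits follow a
    symmetric k-state Mk process.  Cells are then masked missing
    independently at rate ``missingness``.
    """
    if rng is None:
        rng = cfg.rng()
    tips = tree.tip_labels
    data: dict[str, object] = {}
    root_value = 100.0 * max(cfg.brownian_sigma, 1.0)
    for j in range(cfg.n_quant_traits):
        values: dict[int, float] = {id(tree.root): root_value}
        out: dict[str, float] = {}
        for node in tree.preorder():
            value = values[id(node)]
            for child in node.children:
                step = rng.normal(0.0, cfg.brownian_sigma * np.sqrt(child.length))
                values[id(child)] = value + step
            if node.is_tip:
                out[node.label] = value  # type: ignore[index]
        data[f"quant_{j + 1}"] = pd.Series(out).loc[tips]
    k = cfg.n_states
    # symmetric Mk: P(stay over t) = 1/k + (1 - 1/k) exp(-k/(k-1) * rate * t)
    for j in range(cfg.n_nominal_traits):
        states: dict[int, int] = {id(tree.root): int(rng.integers(k))}
        out_s: dict[str, str] = {}
        for node in tree.preorder():
            state = states[id(node)]
            for child in node.children:
                p_stay = 1.0 / k + (1.0 - 1.0 / k) * np.exp(
                    -k / (k - 1) * cfg.mk_rate * child.length
                )
                if rng.random() < p_stay:
                    states[id(child)] = state
                else:
                    others = [s for s in range(k) if s != state]
                    states[id(child)] = others[int(rng.integers(k - 1))]
            if node.is_tip:
                out_s[node.label] = f"s{state}"  # type: ignore[index]
        data[f"nominal_{j + 1}"] = pd.Series(out_s).loc[tips]
    table = pd.DataFrame(data, index=tips)
    table.index.name = "species"
    if cfg.missingness > 0:
        mask = rng.random(table.shape) < cfg.missingness
        table = table.mask(mask)
    return table


def simulate_communities(
    tree: PhyloTree, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> CommunityTable:
    """Communities as phylogenetically clustered subsets of the pool.

    Per community: richness k ~ Uniform[lo, hi]; a seed species chosen
    uniformly; the remaining k-1 members sampled without replacement with
    weight exp(-alpha * patristic distance to the seed); integer abundances
    from a log-normal (sigma = ``abundance_sigma``).
    """
    if rng is None:
        rng = cfg.rng()
    lo, hi = cfg.richness_range
    labels = tree.tip_labels
    n = len(labels)
    if hi > n:
        raise ConfigError(f"richness upper bound {hi} exceeds pool size {n}")
    D = patristic_matrix(tree).to_numpy()
    counts: dict[str, dict[str, int]] = {}
    for c in range(cfg.n_communities):
        k = int(rng.integers(lo, hi + 1))
        seed_idx = int(rng.integers(n))
        if cfg.clustering_alpha > 0:
            w = np.exp(-cfg.clustering_alpha * D[:, seed_idx])
        else:
            w = np.ones(n)
        w[seed_idx] = 0.0
        p = w / w.sum()
        others = rng.choice(n, size=k - 1, replace=False, p=p)
        members = np.concatenate([[seed_idx], others])
        abund = rng.lognormal(0.0, cfg.abundance_sigma, size=k)
        abund = np.maximum(1, np.round(10.0 * abund)).astype(int)
        counts[f"comm{c + 1:04d}"] = {
            labels[i]: int(a) for i, a in zip(members, abund)
        }
    return CommunityTable(counts, provenance="FULL")


@dataclass
class SyntheticBundle:
    """All generated inputs for one synthetic study."""

    config: SimConfig
    ensemble: TreeEnsemble
    traits: pd.DataFrame
    trait_spec: TraitTypeSpec
    communities: CommunityTable

    @property
    def base_tree(self) -> PhyloTree:
        return self.ensemble[0]


def simulate_bundle(cfg: SimConfig) -> SyntheticBundle:
    """Generate the full input set (ensemble, traits, communities) from one
    seeded RNG stream."""
    rng = cfg.rng()
    tree_rng, trait_rng, comm_rng = rng.spawn(3)
    ensemble = simulate_tree_ensemble(cfg, tree_rng)
    base = ensemble[0]
    traits = simulate_traits(base, cfg, trait_rng)
    communities = simulate_communities(base, cfg, comm_rng)
    return SyntheticBundle(cfg, ensemble, traits, make_trait_spec(cfg), communities)


def write_bundle(bundle: SyntheticBundle, outdir: str) -> dict[str, str]:
    """Write the bundle in the file formats the pipeline consumes.

    Returns the paths written: a multi-tree newick file, a survey CSV
    (site,species,count), a trait CSV and a trait-type JSON.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "trees": os.path.join(outdir, "trees.nwk"),
        "communities": os.path.join(outdir, "communities.csv"),
        "traits": os.path.join(outdir, "traits.csv"),
        "trait_spec": os.path.join(outdir, "trait_types.json"),
    }
    write_trees(bundle.ensemble, paths["trees"])
    bundle.communities.to_csv(paths["communities"])
    bundle.traits.to_csv(paths["traits"])
    bundle.trait_spec.to_file(paths["trait_spec"])
    return paths
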