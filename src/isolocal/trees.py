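"""Species-level evolutionary-isolation metrics on rooted phylogenies.

Implements the three isolation scores compared by the pipeline —

* **ED** (evolutionary distinctiveness, "fair proportion"): each edge's
  length is split equally among the tips descending from it, and a tip's
  score is the sum of its shares along the root-to-tip path;
* **PE** (pendant edge / unique PD contribution): the length of a tip's
  terminal branch;
* **APD** (average pairwise distance): the mean patristic (path-length)
  distance from a tip to every other tip;

plus Faith's phylogenetic diversity (PD) of a species set, community
sub-tree pruning, and median aggregation of scores over an ensemble of
replicate trees on one tip set.

The PD convention is *rooted*: the spanning subtree of a set includes the
path from the set's most recent common ancestor up to the tree root, so a
single lineage contributes positive PD and ``sum(ED) == PD(all tips)``
exactly.  An MRCA-rooted variant is available via ``rooted=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EnsembleMismatchError,
    TreeFormatError,
    UnknownSpeciesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

METRICS = ("ED", "PE", "APD")


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class Node:
    """A node of a rooted phylogeny.

    ``length`` is the length of the edge connecting the node to its parent
    (for the root: an optional root edge, usually 0).
    """

    length: float = 0.0
    label: str | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A rooted phylogeny with branch lengths and uniquely labelled tips."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # -- traversal helpers (iterative: safe on pectinate trees) -------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    # -- basic properties ----------------------------------------------------

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def total_length(self) -> float:
        return float(sum(n.length for n in self.preorder()))

    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.preorder():
            if node.length < 0:
                raise ValidationError(f"negative edge length {node.length}")
            if node.is_tip:
                if not node.label:
                    raise ValidationError("unlabelled tip")
                labels.append(node.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")

    def copy(self) -> "PhyloTree":
        def _copy(node: Node) -> Node:
            return Node(node.length, node.label, [_copy(c) for c in node.children])

        return PhyloTree(_copy(self.root), validate=False)

    # -- serialisation -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises many error types
            raise TreeFormatError(f"cannot parse newick: {exc}") from exc
        return _from_dendropy(dtree)

    def to_newick(self) -> str:
        def _fmt(node: Node) -> str:
            label = _quote_label(node.label) if node.label else ""
            if node.is_tip:
                return f"{label}:{node.length:.12g}"
            inner = ",".join(_fmt(c) for c in node.children)
            return f"({inner}){label}:{node.length:.12g}"

        root = self.root
        inner = ",".join(_fmt(c) for c in root.children) if root.children else _fmt(root)
        suffix = f":{root.length:.12g}" if root.length else ""
        return f"({inner}){suffix};"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips, length {self.total_length():.4g}>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def conv(dnode: dendropy.Node) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return Node(float(length), label, [conv(c) for c in dnode.child_nodes()])

    return PhyloTree(conv(dtree.seed_node))


# ---------------------------------------------------------------------------
# ensembles


@dataclass
class TreeEnsemble:
    """An ordered set of replicate trees sharing one identical tip set."""

    trees: list[PhyloTree]
    id: str = "ensemble"

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError("ensemble must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for i, tree in enumerate(self.trees[1:], start=2):
            tips = set(tree.tip_labels)
            if tips != ref:
                diff = sorted(tips.symmetric_difference(ref))
                raise EnsembleMismatchError(
                    f"tree {i} tip set differs from tree 1; "
                    f"symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    @property
    def tip_labels(self) -> list[str]:
        return self.trees[0].tip_labels


def read_trees(path: str, format: str = "newick", id: str = "ensemble") -> TreeEnsemble:
    """Read a single- or multi-tree file into a :class:`TreeEnsemble`.

    ``format`` is ``"newick"`` (one tree per line) or ``"nexus"`` (TREES
    block).  Branch lengths are preserved as parsed; missing lengths are
    treated as 0.  All trees must share one identical tip-label set.
    """
    if format not in ("newick", "nexus"):
        raise ValidationError(f"unsupported tree format: {format!r}")
    try:
        dtrees = dendropy.TreeList.get(
            path=str(path), schema=format, preserve_underscores=True
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if len(dtrees) == 0:
        raise TreeFormatError(f"no trees found in {path}")
    return TreeEnsemble([_from_dendropy(t) for t in dtrees], id=id)


def write_trees(ensemble: TreeEnsemble | Iterable[PhyloTree], path: str) -> None:
    """Write trees as newick, one per line."""
    with open(path, "w") as fh:
        for tree in ensemble:
            fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# per-tree metrics


def _require_tips(tree: PhyloTree, n: int, what: str) -> list[Node]:
    tips = tree.tips
    if len(tips) < n:
        raise DegenerateInputError(f"{what} requires >= {n} tips, got {len(tips)}")
    return tips


def _n_tips_below(tree: PhyloTree) -> dict[int, int]:
    """Number of tips descending through each node's parent edge."""
    counts: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_tip:
            counts[id(node)] = 1
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
    return counts


def fair_proportion_ed(tree: PhyloTree) -> pd.Series:
    """Fair-proportion evolutionary distinctiveness for every tip.

    ED(i) = sum over edges *e* on the root-to-tip path of
    ``length(e) / ntips(e)``, so the per-tip scores partition the total tree
    length: ``sum(ED) == total branch length``.
    """
    _require_tips(tree, 2, "fair-proportion ED")
    counts = _n_tips_below(tree)
    acc: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder():
        parent_acc = acc.get(id(node), 0.0)  # root primed below
        share = node.length / counts[id(node)]
        total = parent_acc + share
        if node.is_tip:
            out[node.label] = total  # type: ignore[index]
        else:
            for child in node.children:
                acc[id(child)] = total
    # note: acc for root's children was set when visiting root, whose own
    # parent_acc defaults to 0 — the (rare) root edge is apportioned too.
    return pd.Series(out, name="ED").loc[tree.tip_labels]


def pendant_edge_pe(tree: PhyloTree) -> pd.Series:
    """Terminal-branch length (pendant edge / unique PD contribution)."""
    tips = _require_tips(tree, 1, "pendant edge")
    return pd.Series({t.label: t.length for t in tips}, name="PE").loc[tree.tip_labels]


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    """All-pairs patristic (cophenetic) distance matrix over tips.

    d(i, j) is the sum of edge lengths on the tree path between tips i and j.
    """
    tips = _require_tips(tree, 1, "patristic matrix")
    labels = [t.label for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    D = np.zeros((n, n))
    # bottom-up: combine per-child (tip index, distance-to-node) arrays
    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder():
        if node.is_tip:
            carry[id(node)] = (
                np.array([index[id(node)]], dtype=np.intp),
                np.zeros(1),
            )
            continue
        groups = []
        for child in node.children:
            idx, dist = carry.pop(id(child))
            groups.append((idx, dist + child.length))
        for a in range(len(groups)):
            ia, da = groups[a]
            for b in range(a + 1, len(groups)):
                ib, db = groups[b]
                block = da[:, None] + db[None, :]
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        carry[id(node)] = (
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]),
        )
    return pd.DataFrame(D, index=labels, columns=labels)


def average_pairwise_apd(tree: PhyloTree, denominator: str = "n-1") -> pd.Series:
    """Mean patristic distance from each tip to all other tips.

    ``denominator="n-1"`` (default) excludes the zero self-distance; ``"n"``
    is provided for compatibility with conventions that include it.
    """
    _require_tips(tree, 2, "APD")
    D = patristic_matrix(tree)
    n = D.shape[0]
    div = n - 1 if denominator == "n-1" else n
    return pd.Series(D.values.sum(axis=1) / div, index=D.index, name="APD")


def _mark_selected(tree: PhyloTree, species: set[str]) -> dict[int, bool]:
    selected: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_tip:
            selected[id(node)] = node.label in species
        else:
            selected[id(node)] = any(selected[id(c)] for c in node.children)
    return selected


def faith_pd(tree: PhyloTree, species: Iterable[str], rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of a species set.

    Sum of edge lengths of the subtree spanning the set.  With
    ``rooted=True`` (default) the subtree includes the path from the set's
    MRCA up to the tree root; with ``rooted=False`` it stops at the MRCA
    (zero for a single species).
    """
    species = set(species)
    if not species:
        raise DegenerateInputError("faith_pd requires a non-empty species set")
    tips = set(tree.tip_labels)
    unknown = species - tips
    if unknown:
        raise UnknownSpeciesError(f"labels not in tree: {sorted(unknown)}")
    selected = _mark_selected(tree, species)
    pd_rooted = sum(n.length for n in tree.preorder() if selected[id(n)])
    if rooted:
        return float(pd_rooted)
    # subtract the path above the MRCA (root edge included)
    above = 0.0
    node = tree.root
    while True:
        above += node.length
        sel_children = [c for c in node.children if selected[id(c)]]
        if len(sel_children) != 1 or node.is_tip:
            break
        node = sel_children[0]
    return float(pd_rooted - above)


def prune_to_community(tree: PhyloTree, species: Iterable[str]) -> PhyloTree:
    """Sub-tree spanning a community's species.

    Keeps the path from the retained tips' MRCA up to the original root
    (matching the rooted PD convention, so the pruned tree's total length
    equals ``faith_pd(tree, species)``).  Degree-2 internal nodes created by
    pruning are suppressed with their edge lengths summed.
    """
    keep = set(species) & set(tree.tip_labels)
    if len(keep) < 2:
        raise DegenerateInputError(
            f"pruning requires >= 2 matching tips, got {len(keep)}"
        )

    def build(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                return Node(node.length, node.label)
            return None
        kept = [c2 for c2 in (build(c) for c in node.children) if c2 is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress the unifurcation: merge this node into its child
            child = kept[0]
            child.length += node.length
            return child
        return Node(node.length, node.label, kept)

    root = tree.root
    kept = [c2 for c2 in (build(c) for c in root.children) if c2 is not None]
    # the root itself is never merged away: the root path is part of the
    # rooted convention (a single surviving child keeps its full edge).
    new_root = Node(root.length, root.label, kept)
    return PhyloTree(new_root)


# ---------------------------------------------------------------------------
# score tables and ensemble aggregation

_METRIC_FUNCS = {
    "ED": fair_proportion_ed,
    "PE": pendant_edge_pe,
    "APD": average_pairwise_apd,
}


def tree_scores(tree: PhyloTree) -> pd.DataFrame:
    """ED, PE and APD for every tip of one tree (columns ED/PE/APD)."""
    return pd.DataFrame(
        {m: _METRIC_FUNCS[m](tree) for m in METRICS}
    )


def median_scores(ensemble: TreeEnsemble, metric: str) -> pd.Series:
    """Per-species median of one metric across the ensemble's trees.

    Even ensemble sizes use the arithmetic midpoint of the two central
    values.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    func = _METRIC_FUNCS[metric]
    labels = ensemble.tip_labels
    mat = np.vstack([func(t).loc[labels].to_numpy() for t in ensemble])
    return pd.Series(np.median(mat, axis=0), index=labels, name=metric)


@dataclass
class ScoreTable:
    """Species-by-metric scores tagged with their scope.

    ``scope`` is ``"GLOBAL"`` for the full species pool or a community id for
    local (pruned sub-tree) scores.  ``scores`` is indexed by species with
    columns ED, PE, APD.
    """

    scope: str
    scores: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [m for m in METRICS if m not in self.scores.columns]
        if missing:
            raise ValidationError(f"score table missing columns {missing}")
        if not np.isfinite(self.scores[list(METRICS)].to_numpy()).all():
            raise ValidationError("score table contains non-finite values")
        self.scores.index = self.scores.index.astype(str)
        self.scores.index.name = "species"

    @property
    def species(self) -> list[str]:
        return list(self.scores.index)

    def metric(self, name: str) -> pd.Series:
        if name not in METRICS:
            raise ValidationError(f"unknown metric {name!r}")
        return self.scores[name]

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.copy()
        df.insert(0, "scope", self.scope)
        df.index.name = "species"
        return df.reset_index()

    @classmethod
    def from_tree(cls, tree: PhyloTree, scope: str = "GLOBAL") -> "ScoreTable":
        return cls(scope, tree_scores(tree))

    @classmethod
    def from_ensemble(cls, ensemble: TreeEnsemble, scope: str = "GLOBAL") -> "ScoreTable":
        df = pd.DataFrame({m: median_scores(ensemble, m) for m in METRICS})
        return cls(scope, df)


def community_score_table(
    ensemble: TreeEnsemble | PhyloTree, species: Iterable[str], scope: str
) -> ScoreTable:
    """Local scores: metrics on the pruned community sub-tree, median over
    the ensemble."""
    if isinstance(ensemble, PhyloTree):
        ensemble = TreeEnsemble([ensemble])
    per_tree = [tree_scores(prune_to_community(t, species)) for t in ensemble]
    labels = per_tree[0].index
    stacked = np.stack([df.loc[labels].to_numpy() for df in per_tree])
    med = pd.DataFrame(np.median(stacked, axis=0), index=labels, columns=per_tree[0].columns)
    return ScoreTable(scope, med)


def write_score_tables(tables: Iterable[ScoreTable], path: str) -> None:
    """CSV with columns species, scope, ED, PE, APD (one row per species per
    scope)."""
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


def read_score_tables(path: str) -> dict[str, ScoreTable]:
    df = pd.read_csv(path)
    needed = {"species", "scope", *METRICS}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"score CSV missing columns {sorted(missing)}")
    out: dict[str, ScoreTable] = {}
    for scope, grp in df.groupby("scope"):
        out[str(scope)] = ScoreTable(
            str(scope), grp.set_index("species")[list(METRICS)]
        )
    return out


# ---------------------------------------------------------------------------
# fast repeated-PD evaluation (used by the removal simulation)


class PDCalculator:
    """Precomputed edge/tip incidence for fast rooted Faith's PD queries.

    Holds, for each edge, its length and the boolean set of tips descending
    through it; PD of any tip subset is then the total length of edges with
    at least one selected descendant.  Supports batched evaluation of many
    subsets at once (columns of an indicator matrix).
    """

    def __init__(self, tree: PhyloTree):
        tips = tree.tips
        self.labels = [t.label for t in tips]
        self.index: Mapping[str, int] = {l: i for i, l in enumerate(self.labels)}
        n = len(tips)
        rows: list[np.ndarray] = []
        lengths: list[float] = []
        carry: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_tip:
                mask = np.zeros(n, dtype=bool)
                mask[self.index[node.label]] = True  # type: ignore[index]
            else:
                mask = np.zeros(n, dtype=bool)
                for c in node.children:
                    mask |= carry.pop(id(c))
            carry[id(node)] = mask
            lengths.append(node.length)
            rows.append(mask)
        self.incidence = np.array(rows)  # (n_edges, n_tips)
        self.lengths = np.asarray(lengths)
        self.total = float(self.lengths.sum())

    def indicator(self, species: Iterable[str]) -> np.ndarray:
        s = np.zeros(len(self.labels), dtype=bool)
        for label in species:
            try:
                s[self.index[label]] = True
            except KeyError:
                raise UnknownSpeciesError(f"label not in tree: {label!r}") from None
        return s

    def pd(self, species: Iterable[str]) -> float:
        s = self.indicator(species)
        if not s.any():
            return 0.0
        covered = self.incidence @ s > 0
        return float(self.lengths @ covered)

    def pd_batch(self, indicators: np.ndarray) -> np.ndarray:
        """PD for each column of a (n_tips, R) boolean indicator matrix."""
        covered = self.incidence @ indicators > 0  # (n_edges, R)
        return self.lengths @ covered
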