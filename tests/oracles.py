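"""Independent brute-force implementations used as oracles.

Everything here is deliberately naive — explicit edge enumeration, all-pairs
path sums, per-pair per-column loops, exhaustive subset enumeration — and
shares no code path with the package's vectorised implementations.
"""

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def _edges(tree):
    """(node, tips_below, path_nodes) for every node; root edge included."""
    out = []

    def walk(node, ancestors):
        path = ancestors + [node]
        if node.is_tip:
            tips = {node.label}
        else:
            tips = set()
            for child in node.children:
                tips |= walk(child, path)
        out.append((node, frozenset(tips), tuple(path)))
        return tips

    walk(tree.root, [])
    return out


def brute_ed(tree):
    """Per-edge apportionment: each edge's length split equally among its
    descendant tips."""
    scores = {label: 0.0 for label in tree.tip_labels}
    for node, tips, _ in _edges(tree):
        share = node.length / len(tips)
        for t in tips:
            scores[t] += share
    return scores


def brute_pe(tree):
    return {t.label: t.length for t in tree.tips}


def _root_paths(tree):
    paths = {}
    for node, tips, path in _edges(tree):
        if node.is_tip:
            paths[node.label] = path
    return paths


def brute_patristic(tree):
    """All-pairs path sums: shared root-path prefix removed."""
    paths = _root_paths(tree)
    labels = tree.tip_labels
    D = {}
    for a in labels:
        for b in labels:
            pa, pb = paths[a], paths[b]
            shared = set(map(id, pa)) & set(map(id, pb))
            d = sum(n.length for n in pa if id(n) not in shared)
            d += sum(n.length for n in pb if id(n) not in shared)
            D[(a, b)] = d
    return D

def brute_apd(tree):
    D = brute_patristic(tree)
    labels = tree.tip_labels
    n = len(labels)
    return {
        a: sum(D[(a, b)] for b in labels if b != a) / (n - 1) for a in labels
    }


def brute_pd(tree, species):
    """Union of root-to-tip paths (rooted convention)."""
    paths = _root_paths(tree)
    union = {}
    for s in species:
        for node in paths[s]:
            union[id(node)] = node.length
    return sum(union.values())


def brute_gower(table: pd.DataFrame, kinds: dict):
    """Per-pair, per-column loop; ordinal columns pre-ranked (mid-ranks).

    Returns a label-keyed dict with None for incomparable pairs.
    """
    labels = list(table.index)
    cols = {}
    for col, kind in kinds.items():
        vals = table[col]
        if kind == "nominal":
            cols[col] = ("nominal", vals, None)
        else:
            x = pd.to_numeric(vals, errors="coerce")
            if kind == "ordinal":
                ranked = x.copy()
                ranked[x.notna()] = stats.rankdata(x.dropna())
                x = ranked
            rng = x.max() - x.min()
            cols[col] = ("numeric", x, rng)
    out = {}
    for a in labels:
        for b in labels:
            if a == b:
                out[(a, b)] = 0.0
                continue
            total, count = 0.0, 0
            for col, (kind, vals, rng) in cols.items():
                va, vb = vals[a], vals[b]
                if pd.isna(va) or pd.isna(vb):
                    continue
                count += 1
                if kind == "nominal":
                    total += 0.0 if va == vb else 1.0
                elif rng and rng > 0:
                    total += abs(va - vb) / rng
            out[(a, b)] = total / count if count else None
    return out


def brute_spearman(x, y):
    """Mid-ranks then Pearson; two-sided p from the t approximation."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    n = len(x)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, p


def brute_bh(pvals):
    """Benjamini-Hochberg step-up by the textbook recipe."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * n / rank_from_top)
        q[i] = prev
    return q


def exhaustive_null_pd_loss(tree, community, m, pd_func):
    """Mean PD loss over all m-subsets removed from the community."""
    community = sorted(community)
    before = pd_func(tree, community)
    losses = []
    for removed in combinations(community, m):
        remaining = [s for s in community if s not in set(removed)]
        after = pd_func(tree, remaining) if remaining else 0.0
        losses.append(before - after)
    return float(np.mean(losses)), losses
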