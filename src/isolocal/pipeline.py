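"""High-level orchestration of the analysis stages.

These functions wire the modules into the full workflow — survey records to
filtered community variants, ensemble median scores, per-community
concordance, and the top-K removal experiment — and are what the CLI and
reproduction script call.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .communities import CommunityTable, FilterConfig, filter_min_richness, \
    reconcile_names, remove_aliens, remove_rare
from .concordance import (
    DEFAULT_PAIRS,
    ConcordanceRecord,
    community_concordance,
    records_to_frame,
    summarize_concordance,
)
from .errors import DegenerateInputError, ValidationError
from .removal import RemovalConfig, RemovalResult, run_removal, summarize_removal
from .traits import (
    TraitDistanceMatrix,
    TraitTypeSpec,
    gower_matrix,
    impute_incomparable_pairs,
    restrict_to_community,
    standardize_quantitative,
    trait_apd,
    trait_uniqueness,
)
from .trees import (
    METRICS,
    PhyloTree,
    ScoreTable,
    TreeEnsemble,
    community_score_table,
)

logger = logging.getLogger(__name__)

VARIANT_KEYS = {"full": "FULL", "no-aliens": "NO_ALIENS", "no-rare": "NO_RARE"}


def prepare_communities(
    table: CommunityTable,
    known: Iterable[str],
    cfg: FilterConfig,
    variant: str = "FULL",
) -> CommunityTable:
    """Richness filter + name reconciliation on FULL, then the requested
    variant (alien or rare removal) derived from it."""
    table = filter_min_richness(table, cfg)
    table = reconcile_names(table, known, cfg)
    if variant == "FULL":
        return table
    if variant == "NO_ALIENS":
        return remove_aliens(table, cfg)
    if variant == "NO_RARE":
        return remove_rare(table, cfg)
    raise ValidationError(f"unknown variant {variant!r}")


def global_trait_matrix(
    trait_table: pd.DataFrame, trait_spec: TraitTypeSpec
) -> TraitDistanceMatrix:
    """Mean-standardise quantitative traits, build the Gower matrix and
    resolve incomparable pairs by the median rule."""
    standardized = standardize_quantitative(trait_table, trait_spec)
    return impute_incomparable_pairs(gower_matrix(standardized, trait_spec))


def concordance_analysis(
    ensemble: TreeEnsemble,
    communities: CommunityTable,
    trait_matrix: Optional[TraitDistanceMatrix] = None,
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    global_scores: Optional[ScoreTable] = None,
) -> list[ConcordanceRecord]:
    """Per-community concordance records for every requested metric pair.

    Local tree scores are medians over the ensemble of metrics on the
    community sub-tree; local TU/TAPD are recomputed on the community's
    restriction of the global trait distance matrix.
    """
    if global_scores is None:
        global_scores = ScoreTable.from_ensemble(ensemble)
    variant = communities.provenance
    needs_traits = any(l in ("TU", "TAPD") for _, l in pairs)
    records: list[ConcordanceRecord] = []
    for site in sorted(communities.sites):
        members = communities.species(site)
        try:
            local = community_score_table(ensemble, members, site)
        except DegenerateInputError:
            logger.warning("community %r too small for local scores; skipped", site)
            continue
        trait_local: Optional[dict[str, pd.Series]] = None
        if needs_traits and trait_matrix is not None:
            t_members = [s for s in members if s in set(trait_matrix.labels)]
            if len(t_members) >= 2:
                sub = restrict_to_community(trait_matrix, t_members, site)
                trait_local = {"TU": trait_uniqueness(sub), "TAPD": trait_apd(sub)}
            else:
                trait_local = {"TU": pd.Series(dtype=float),
                               "TAPD": pd.Series(dtype=float)}
        elif needs_traits:
            trait_local = {"TU": pd.Series(dtype=float),
                           "TAPD": pd.Series(dtype=float)}
        records.extend(
            community_concordance(
                global_scores, local, trait_local, members, pairs, site, variant
            )
        )
    return records


def removal_analysis(
    communities: CommunityTable,
    tree: PhyloTree,
    trait_matrix: Optional[TraitDistanceMatrix],
    global_scores: ScoreTable,
    k: int = 500,
    replicates: int = 500,
    seed: Optional[int] = None,
    metrics: Sequence[str] = METRICS,
    alpha: float = 0.05,
) -> list[RemovalResult]:
    """The removal experiment for each ranking metric, with independent
    seeded RNG streams per metric."""
    rng = np.random.default_rng(seed)
    results: list[RemovalResult] = []
    for metric, metric_rng in zip(metrics, rng.spawn(len(metrics))):
        cfg = RemovalConfig(
            k=k, replicates=replicates, metric=metric, seed=seed, alpha=alpha
        )
        results.extend(
            run_removal(communities, tree, trait_matrix, global_scores, cfg,
                        rng=metric_rng)
        )
    return results


__all__ = [
    "prepare_communities",
    "global_trait_matrix",
    "concordance_analysis",
    "removal_analysis",
    "records_to_frame",
    "summarize_concordance",
    "summarize_removal",
    "VARIANT_KEYS",
]
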