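"""Top-K species-removal experiment with a random-removal null.

Species are ranked by a global isolation metric; the top-K set is removed
from every community and the biodiversity change measured as

* **PD loss** — rooted Faith's PD of the community minus PD of the depleted
  community (tree-length units, >= 0);
* **TAPD change** — mean pairwise trait distance of the community minus
  that of the depleted community (positive: the remaining species are more
  similar on average).

For each community the same number of species is removed uniformly at
random (R replicates) to form a null distribution; one-sided ("greater")
empirical p-values use the add-one estimator and are FDR-adjusted across
communities with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityTable
from .errors import DegenerateInputError, ValidationError
from .traits import TraitDistanceMatrix
from .trees import METRICS, PDCalculator, PhyloTree, ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class RemovalConfig:
    """Parameters of the removal experiment."""

    k: int = 500
    replicates: int = 500
    metric: str = "ED"
    seed: Optional[int] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.metric not in METRICS:
            raise ValidationError(f"metric must be one of {METRICS}")


@dataclass
class RemovalResult:
    """Observed and null removal effects for one community."""

    community: str
    metric: str
    m: int
    pd_loss: float
    tapd_change: Optional[float]
    pd_null_mean: float
    pd_null_sd: float
    tapd_null_mean: Optional[float]
    tapd_null_sd: Optional[float]
    p_pd: Optional[float]
    p_tapd: Optional[float]
    q_pd: Optional[float] = None
    q_tapd: Optional[float] = None
    variant: str = "FULL"


def top_k_species(global_scores: ScoreTable, metric: str, k: int) -> list[str]:
    """The K species with the largest global metric values.

    Ties at the cutoff are broken by label order (deterministic, logged).
    """
    values = global_scores.metric(metric)
    if k > len(values):
        raise ValidationError(f"k={k} exceeds pool size {len(values)}")
    order = sorted(values.index, key=lambda s: (-values[s], s))
    top = order[:k]
    if k < len(order) and values[order[k - 1]] == values[order[k]]:
        logger.info(
            "top_k_species: tie at the k=%d cutoff (%s = %g) broken by label order",
            k, metric, values[order[k]],
        )
    return top


def _mean_pairwise(values: np.ndarray) -> float:
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(values[iu].mean())


def observed_removal(
    community: Iterable[str],
    tree: PhyloTree | PDCalculator,
    traits: Optional[TraitDistanceMatrix],
    topset: Iterable[str],
) -> tuple[float, Optional[float], int]:
    """PD loss, TAPD change and overlap m for one community and one top-K
    set.

    TAPD change is ``None`` when fewer than 2 species with trait data remain
    after removal (or exist before it).
    """
    calc = tree if isinstance(tree, PDCalculator) else PDCalculator(tree)
    members = sorted(set(community) & set(calc.labels))
    if len(members) < 2:
        raise DegenerateInputError("community needs >= 2 species on the tree")
    topset = set(topset)
    removed = [s for s in members if s in topset]
    remaining = [s for s in members if s not in topset]
    m = len(removed)
    pd_before = calc.pd(members)
    pd_after = calc.pd(remaining) if remaining else 0.0
    pd_loss = pd_before - pd_after

    tapd_change: Optional[float] = None
    if traits is not None:
        pos = {l: i for i, l in enumerate(traits.labels)}
        t_members = [s for s in members if s in pos]
        t_remaining = [s for s in t_members if s not in topset]
        if len(t_members) >= 2 and len(t_remaining) >= 2:
            idx_b = np.array([pos[s] for s in t_members])
            idx_a = np.array([pos[s] for s in t_remaining])
            before = _mean_pairwise(traits.values[np.ix_(idx_b, idx_b)])
            after = _mean_pairwise(traits.values[np.ix_(idx_a, idx_a)])
            tapd_change = before - after
        else:
            logger.debug("TAPD change undefined for a community (too few species)")
    return float(pd_loss), tapd_change, m


def _random_subsets(n: int, m: int, replicates: int, rng: np.random.Generator) -> np.ndarray:
    """(replicates, m) indices of uniform random m-subsets of range(n)."""
    keys = rng.random((replicates, n))
    return np.argpartition(keys, m - 1, axis=1)[:, :m] if m > 0 else np.empty(
        (replicates, 0), dtype=int
    )


def random_removal_null(
    community: Iterable[str],
    tree: PhyloTree | PDCalculator,
    traits: Optional[TraitDistanceMatrix],
    m: int,
    cfg: RemovalConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions of PD loss and TAPD change under uniform random
    removal of m species (R replicates, without replacement, seeded).

    Returns ``(pd_losses, tapd_changes)`` of length R; TAPD entries are NaN
    where the depleted community keeps fewer than 2 species with trait data.
    With m = 0 both vectors are all zeros.
    """
    calc = tree if isinstance(tree, PDCalculator) else PDCalculator(tree)
    members = sorted(set(community) & set(calc.labels))
    n = len(members)
    if not 0 <= m <= n:
        raise ValidationError(f"m={m} outside [0, {n}]")
    R = cfg.replicates
    if m == 0:
        return np.zeros(R), np.zeros(R)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    removed_idx = _random_subsets(n, m, R, rng)  # indices into `members`

    # PD: batched over replicates via the edge-incidence matrix
    base = calc.indicator(members)
    member_cols = np.array([calc.index[s] for s in members])
    keep = np.repeat(base[:, None], R, axis=1)  # (n_tips, R)
    rows = member_cols[removed_idx]  # (R, m) tip indices
    keep[rows.T, np.arange(R)[None, :].repeat(m, axis=0)] = False
    pd_before = calc.pd(members)
    pd_losses = pd_before - calc.pd_batch(keep)

    # TAPD: quadratic-form trick on the community trait submatrix
    tapd_changes = np.zeros(R)
    if traits is not None:
        pos = {l: i for i, l in enumerate(traits.labels)}
        t_mask = np.array([s in pos for s in members])
        t_members = [s for s in members if s in pos]
        if len(t_members) >= 2:
            idx_t = np.array([pos[s] for s in t_members])
            D = traits.values[np.ix_(idx_t, idx_t)]
            before = _mean_pairwise(D)
            # indicator of kept species within the trait-covered subset
            member_to_t = np.full(n, -1)
            member_to_t[np.flatnonzero(t_mask)] = np.arange(len(t_members))
            K = np.ones((len(t_members), R), dtype=float)
            rem_t = member_to_t[removed_idx]  # (R, m), -1 = no trait data
            for r in range(R):
                sel = rem_t[r]
                K[sel[sel >= 0], r] = 0.0
            kept_counts = K.sum(axis=0)
            q = np.einsum("ir,ir->r", K, D @ K)  # sum over kept ordered pairs
            with np.errstate(invalid="ignore", divide="ignore"):
                after = q / (kept_counts * (kept_counts - 1))
            tapd_changes = np.where(kept_counts >= 2, before - after, np.nan)
        else:
            tapd_changes = np.full(R, np.nan)
    return np.asarray(pd_losses, dtype=float), tapd_changes


def empirical_pvalue(observed: float, null: Sequence[float]) -> float:
    """One-sided ("greater") add-one empirical p-value:
    p = (1 + #{null >= observed}) / (R + 1).  NaN null entries are dropped."""
    null = np.asarray(null, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValidationError("empirical_pvalue needs a non-empty null")
    return float((1 + np.sum(null >= observed)) / (null.size + 1))


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in (0, 1]")
    return stats.false_discovery_control(p, method="bh")


def run_removal(
    communities: CommunityTable,
    tree: PhyloTree,
    traits: Optional[TraitDistanceMatrix],
    global_scores: ScoreTable,
    cfg: RemovalConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[RemovalResult]:
    """The full experiment for one metric over every community.

    Each community gets its own child RNG stream (deterministic under
    ``cfg.seed`` regardless of community order).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    topset = set(top_k_species(global_scores, cfg.metric, cfg.k))
    calc = PDCalculator(tree)
    results: list[RemovalResult] = []
    site_rngs = rng.spawn(len(communities.sites))
    for site, site_rng in zip(sorted(communities.sites), site_rngs):
        members = communities.species(site)
        pd_loss, tapd_change, m = observed_removal(members, calc, traits, topset)
        pd_null, tapd_null = random_removal_null(
            members, calc, traits, m, cfg, rng=site_rng
        )
        tapd_ok = ~np.isnan(tapd_null)
        p_pd = empirical_pvalue(pd_loss, pd_null)
        p_tapd = (
            empirical_pvalue(tapd_change, tapd_null)
            if tapd_change is not None and tapd_ok.any()
            else None
        )
        results.append(
            RemovalResult(
                community=site,
                metric=cfg.metric,
                m=m,
                pd_loss=pd_loss,
                tapd_change=tapd_change,
                pd_null_mean=float(np.mean(pd_null)),
                pd_null_sd=float(np.std(pd_null, ddof=1)) if len(pd_null) > 1 else 0.0,
                tapd_null_mean=float(np.nanmean(tapd_null)) if tapd_ok.any() else None,
                tapd_null_sd=(
                    float(np.nanstd(tapd_null, ddof=1)) if tapd_ok.sum() > 1 else None
                ),
                p_pd=p_pd,
                p_tapd=p_tapd,
                variant=communities.provenance,
            )
        )
    # BH across communities, separately for the PD and TAPD tests
    q_pd = fdr_adjust([r.p_pd for r in results])
    for r, q in zip(results, q_pd):
        r.q_pd = float(q)
    with_tapd = [r for r in results if r.p_tapd is not None]
    if with_tapd:
        q_tapd = fdr_adjust([r.p_tapd for r in with_tapd])
        for r, q in zip(with_tapd, q_tapd):
            r.q_tapd = float(q)
    return results


def results_to_frame(results: Iterable[RemovalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "community": r.community,
                "variant": r.variant,
                "metric": r.metric,
                "m": r.m,
                "pd_loss": r.pd_loss,
                "pd_null_mean": r.pd_null_mean,
                "pd_null_sd": r.pd_null_sd,
                "tapd_change": r.tapd_change,
                "tapd_null_mean": r.tapd_null_mean,
                "tapd_null_sd": r.tapd_null_sd,
                "p_pd": r.p_pd,
                "q_pd": r.q_pd,
                "p_tapd": r.p_tapd,
                "q_tapd": r.q_tapd,
            }
            for r in results
        ]
    )


def summarize_removal(
    results: Iterable[RemovalResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-metric summary: mean observed vs mean null PD loss and TAPD
    change, mean q and share of communities significant at alpha."""
    frame = results_to_frame(results)
    if frame.empty:
        raise ValidationError("no removal results to summarize")
    rows = []
    for metric, grp in frame.groupby("metric", sort=False):
        tapd = grp.dropna(subset=["tapd_change"])
        rows.append(
            {
                "metric": metric,
                "n_communities": len(grp),
                "mean_pd_loss": grp["pd_loss"].mean(),
                "mean_null_pd_loss": grp["pd_null_mean"].mean(),
                "mean_tapd_change": tapd["tapd_change"].mean() if len(tapd) else np.nan,
                "mean_null_tapd_change": (
                    tapd["tapd_null_mean"].mean() if len(tapd) else np.nan
                ),
                "mean_q_pd": grp["q_pd"].mean(),
                "prop_sig_pd": float((grp["q_pd"] < alpha).mean()),
                "mean_q_tapd": tapd["q_tapd"].mean() if len(tapd) else np.nan,
                "prop_sig_tapd": (
                    float((tapd["q_tapd"] < alpha).mean()) if len(tapd) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("metric")
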