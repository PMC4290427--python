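"""Per-community rank concordance between global and local isolation scores.

For every community the pipeline computes Spearman's rank correlation
between each global metric (ED, PE, APD, computed on the species-pool tree)
and each local metric (ED, PE, APD on the community sub-tree; TU and TAPD
on the community trait submatrix), then summarises across communities:
mean rho, s.d. of rho and the proportion of communities significant at a
chosen alpha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedCorrelationError, ValidationError
from .trees import METRICS, ScoreTable

logger = logging.getLogger(__name__)

GLOBAL_METRICS = METRICS  # ("ED", "PE", "APD")
LOCAL_METRICS = ("ED", "PE", "APD", "TU", "TAPD")

#: all 15 global x local metric pairs analysed by default
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (g, l) for g in GLOBAL_METRICS for l in LOCAL_METRICS
)


def pair_label(global_metric: str, local_metric: str) -> str:
    return f"{global_metric}~local_{local_metric}"


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with mid-rank ties and the two-sided t-approximation
    p-value (t = rho*sqrt((n-2)/(1-rho^2)), n-2 d.f.); p = 0 when |rho| = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_rho needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise UndefinedCorrelationError(f"need >= 3 observations, got {len(x)}")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    # perfectly concordant/discordant ranks: exact +-1, p = 0 by convention
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.array_equal(rx, ry):
        return 1.0, 0.0
    if np.array_equal(rx, len(ry) + 1 - ry):
        return -1.0, 0.0
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p = 0.0 if abs(rho) >= 1.0 else float(res.pvalue)
    return rho, p


@dataclass
class ConcordanceRecord:
    """Spearman correlation between one global and one local metric in one
    community."""

    community: str
    global_metric: str
    local_metric: str
    n: int
    rho: float
    p: float
    variant: str = "FULL"
    defined: bool = True

    @property
    def pair(self) -> str:
        return pair_label(self.global_metric, self.local_metric)


def community_concordance(
    global_scores: ScoreTable,
    local_scores: Optional[ScoreTable],
    trait_local: Optional[Mapping[str, pd.Series]],
    community: Iterable[str],
    pairs: Sequence[tuple[str, str]] = DEFAULT_PAIRS,
    community_id: str = "community",
    variant: str = "FULL",
) -> list[ConcordanceRecord]:
    """One :class:`ConcordanceRecord` per requested (global, local) metric
    pair, vectors aligned by species label.

    Local tree metrics come from ``local_scores``; local TU/TAPD from
    ``trait_local`` (mapping metric name -> species series).  Species
    missing from either side of a pair are excluded pairwise; pairs with
    fewer than 3 shared species or a constant vector yield a record with
    ``defined=False`` (excluded from summaries).
    """
    community = {str(s) for s in community}
    records: list[ConcordanceRecord] = []
    for gmetric, lmetric in pairs:
        if gmetric not in GLOBAL_METRICS or lmetric not in LOCAL_METRICS:
            raise ValidationError(f"unknown metric pair ({gmetric}, {lmetric})")
        gvec = global_scores.metric(gmetric)
        if lmetric in METRICS:
            if local_scores is None:
                raise ValidationError(f"pair needs local tree scores: {lmetric}")
            lvec = local_scores.metric(lmetric)
        else:
            if trait_local is None or lmetric not in trait_local:
                raise ValidationError(f"pair needs local trait scores: {lmetric}")
            lvec = trait_local[lmetric]
        shared = sorted(community & set(gvec.index) & set(lvec.index))
        record = ConcordanceRecord(
            community_id, gmetric, lmetric, len(shared), np.nan, np.nan, variant, False
        )
        if len(shared) >= 3:
            try:
                rho, p = spearman_rho(
                    gvec.loc[shared].to_numpy(), lvec.loc[shared].to_numpy()
                )
                record = ConcordanceRecord(
                    community_id, gmetric, lmetric, len(shared), rho, p, variant, True
                )
            except UndefinedCorrelationError as exc:
                logger.debug(
                    "community %s pair %s~%s undefined: %s",
                    community_id, gmetric, lmetric, exc,
                )
        records.append(record)
    return records


def records_to_frame(records: Iterable[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "community": r.community,
                "variant": r.variant,
                "pair": r.pair,
                "n": r.n,
                "rho": r.rho,
                "p": r.p,
                "defined": r.defined,
            }
            for r in records
        ]
    )


def summarize_concordance(
    records: Iterable[ConcordanceRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Across-community summary per metric pair: mean rho, s.d. of rho and
    the proportion of communities with p < alpha.

    Undefined records are excluded; a pair with no defined record raises.
    A single defined record yields s.d. 0 with a warning.
    """
    records = list(records)
    if not records:
        raise ValidationError("no concordance records to summarize")
    rows = []
    frame = records_to_frame(records)
    for pair, grp in frame.groupby("pair", sort=False):
        ok = grp[grp["defined"]]
        if ok.empty:
            raise ValidationError(f"pair {pair}: no defined concordance records")
        rhos = ok["rho"].to_numpy()
        if len(rhos) == 1:
            warnings.warn(f"pair {pair}: single community, s.d. set to 0")
            sd = 0.0
        else:
            sd = float(np.std(rhos, ddof=1))
        rows.append(
            {
                "pair": pair,
                "n_communities": len(rhos),
                "mean_rho": float(np.mean(rhos)),
                "sd_rho": sd,
                "prop_significant": float(np.mean(ok["p"].to_numpy() < alpha)),
            }
        )
    return pd.DataFrame(rows).set_index("pair")
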