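"""Mixed-type trait distances and trait-based isolation metrics.

Species are compared with the Gower coefficient: per-trait distances
(range-normalised absolute differences for quantitative and ordinal traits,
simple mismatch for nominal traits) averaged over the traits for which both
species have data.  Pairs of species with *no* trait in common are
"incomparable" and are assigned the median of all computable pairwise
distances, flagged in an imputation mask.

From the resulting distance matrix two species-level metrics are derived:

* **TU** (trait uniqueness) — minimum distance to any other species in
  scope;
* **TAPD** (trait average pairwise distance) — mean distance to all other
  species in scope.

"Scope" is either the global species pool or one community; local values
reuse the globally computed pairwise distances restricted to the community
(a ``renormalize`` switch recomputes Gower ranges within the community
instead).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    ConfigError,
    DegenerateInputError,
    ImputationError,
    StandardizationError,
    UnknownSpeciesError,
    ValidationError,
)

logger = logging.getLogger(__name__)

QUANTITATIVE = "quantitative"
ORDINAL = "ordinal"
NOMINAL = "nominal"
_KINDS = (QUANTITATIVE, ORDINAL, NOMINAL)

_NA_VALUES = ("", "NA")


@dataclass
class TraitTypeSpec:
    """Declares, for every trait column, its measurement type.

    ``kinds`` maps column name -> "quantitative" | "ordinal" | "nominal";
    ``standardize`` flags quantitative columns for division by their mean.
    """

    kinds: dict[str, str]
    standardize: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, kind in self.kinds.items():
            if kind not in _KINDS:
                raise ConfigError(f"column {col!r}: unknown trait kind {kind!r}")
        for col in self.standardize:
            if col not in self.kinds:
                raise ConfigError(f"standardize flag for undeclared column {col!r}")
        for col, kind in self.kinds.items():
            self.standardize.setdefault(col, kind == QUANTITATIVE)

    def validate_table(self, table: pd.DataFrame) -> None:
        declared = set(self.kinds)
        present = set(table.columns)
        if declared != present:
            raise ConfigError(
                f"trait spec/table mismatch; undeclared: {sorted(present - declared)}, "
                f"missing: {sorted(declared - present)}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "TraitTypeSpec":
        kinds: dict[str, str] = {}
        standardize: dict[str, bool] = {}
        for col, val in mapping.items():
            if isinstance(val, str):
                kinds[col] = val
            elif isinstance(val, Mapping):
                kinds[col] = str(val.get("kind", ""))
                if "standardize" in val:
                    standardize[col] = bool(val["standardize"])
            else:
                raise ConfigError(f"bad trait spec entry for {col!r}: {val!r}")
        return cls(kinds, standardize)

    @classmethod
    def from_file(cls, path: str) -> "TraitTypeSpec":
        with open(path) as fh:
            text = fh.read()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ConfigError(f"trait spec in {path} must be a mapping")
        return cls.from_mapping(data)

    def to_file(self, path: str) -> None:
        payload = {
            col: {"kind": kind, "standardize": self.standardize[col]}
            for col, kind in self.kinds.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_trait_table(path: str) -> pd.DataFrame:
    """Trait CSV with species labels in the first column; missing values are
    empty cells or "NA"."""
    df = pd.read_csv(
        path, index_col=0, na_values=list(_NA_VALUES), keep_default_na=False
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate species in trait table: {dupes}")
    df.index = df.index.astype(str)
    return df


def standardize_quantitative(
    table: pd.DataFrame, spec: TraitTypeSpec, center: bool = False
) -> pd.DataFrame:
    """Divide flagged quantitative columns by their (non-missing) mean.

    ``center=True`` subtracts the mean instead (off by default: Gower range
    normalisation wants non-negative comparable scales).  Missing cells stay
    missing.
    """
    spec.validate_table(table)
    out = table.copy()
    for col, kind in spec.kinds.items():
        if kind != QUANTITATIVE or not spec.standardize[col]:
            continue
        vals = pd.to_numeric(out[col], errors="coerce")
        mean = vals.mean()
        if pd.isna(mean):
            raise StandardizationError(f"column {col!r} has no non-missing values")
        if not center and abs(mean) < 1e-12:
            raise StandardizationError(f"column {col!r} has zero mean")
        out[col] = vals - mean if center else vals / mean
    return out


@dataclass
class TraitDistanceMatrix:
    """Symmetric Gower distance matrix with an imputation mask.

    ``values[i, j]`` in [0, 1] (NaN while a pair is still incomparable);
    ``imputed`` marks pairs filled by the median rule; ``scope`` is
    ``"GLOBAL"`` or a community id.
    """

    labels: list[str]
    values: np.ndarray
    imputed: np.ndarray
    scope: str = "GLOBAL"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n) or self.imputed.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate species labels in distance matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def incomparable(self) -> np.ndarray:
        return np.isnan(self.values)

    def _index_of(self, species: Iterable[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = []
        for s in species:
            if s not in pos:
                raise UnknownSpeciesError(f"label not in distance matrix: {s!r}")
            idx.append(pos[s])
        return np.asarray(sorted(idx), dtype=np.intp)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str, scope: str = "GLOBAL") -> "TraitDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        return cls(
            [str(l) for l in df.index],
            values,
            np.zeros_like(values, dtype=bool),
            scope,
        )


def gower_matrix(table: pd.DataFrame, spec: TraitTypeSpec) -> TraitDistanceMatrix:
    """Gower mixed-type distance over all species pairs.

    Per pair, the mean over traits where both species are non-missing of:
    quantitative/ordinal |x_i - x_j| / range (ordinals on a mid-rank scale),
    nominal 0/1 mismatch.  Zero-range columns contribute distance 0 (with a
    warning).  Pairs with no shared trait are left NaN (incomparable) for
    :func:`impute_incomparable_pairs` to resolve.
    """
    spec.validate_table(table)
    n = len(table)
    if n < 2:
        raise DegenerateInputError(f"Gower matrix requires >= 2 species, got {n}")
    labels = [str(l) for l in table.index]
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col, kind in spec.kinds.items():
        raw = table[col]
        if kind == NOMINAL:
            present = raw.notna().to_numpy()
            codes = pd.factorize(raw)[0]  # -1 for missing, irrelevant under mask
            comp = np.outer(present, present)
            diff = (codes[:, None] != codes[None, :]).astype(float)
            num += np.where(comp, diff, 0.0)
            den += comp
            continue
        x = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        present = ~np.isnan(x)
        if kind == ORDINAL:
            ranked = np.full(n, np.nan)
            ranked[present] = rankdata(x[present])  # mid-ranks
            x = ranked
        comp = np.outer(present, present)
        if present.sum() == 0:
            continue
        rng = np.nanmax(x) - np.nanmin(x)
        if rng == 0:
            warnings.warn(
                f"trait column {col!r} has zero range; contributes 0 distance",
                stacklevel=2,
            )
            den += comp
            continue
        with np.errstate(invalid="ignore"):
            diff = np.abs(x[:, None] - x[None, :]) / rng
        num += np.where(comp, diff, 0.0)
        den += comp
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    np.fill_diagonal(values, 0.0)
    n_incomp = int(np.isnan(values).sum() // 2)
    if n_incomp:
        logger.info("gower_matrix: %d incomparable species pairs", n_incomp)
    return TraitDistanceMatrix(labels, values, np.zeros((n, n), dtype=bool))


def impute_incomparable_pairs(matrix: TraitDistanceMatrix) -> TraitDistanceMatrix:
    """Assign incomparable pairs the median of all computable pairwise
    distances and mark them imputed."""
    values = matrix.values.copy()
    off = ~np.eye(matrix.n, dtype=bool)
    computable = off & ~np.isnan(values)
    if not computable.any():
        raise ImputationError("no computable species pair to impute from")
    iu = np.triu_indices(matrix.n, k=1)
    upper = values[iu]
    median = float(np.median(upper[~np.isnan(upper)]))
    incomp = off & np.isnan(values)
    values[incomp] = median
    imputed = matrix.imputed | incomp
    return TraitDistanceMatrix(matrix.labels, values, imputed, matrix.scope)


def _require_complete(matrix: TraitDistanceMatrix, what: str) -> np.ndarray:
    if matrix.n < 2:
        raise DegenerateInputError(f"{what} requires >= 2 species in scope")
    if np.isnan(matrix.values).any():
        raise ValidationError(
            f"{what}: matrix has incomparable pairs; run impute_incomparable_pairs"
        )
    return matrix.values


def trait_uniqueness(matrix: TraitDistanceMatrix) -> pd.Series:
    """TU(i): minimum distance from species i to any other species."""
    values = _require_complete(matrix, "trait uniqueness")
    masked = values + np.where(np.eye(matrix.n, dtype=bool), np.inf, 0.0)
    return pd.Series(masked.min(axis=1), index=matrix.labels, name="TU")


def trait_apd(matrix: TraitDistanceMatrix) -> pd.Series:
    """TAPD(i): mean distance from species i to all other species."""
    values = _require_complete(matrix, "trait APD")
    return pd.Series(
        values.sum(axis=1) / (matrix.n - 1), index=matrix.labels, name="TAPD"
    )


def mean_pairwise_distance(matrix: TraitDistanceMatrix) -> float:
    """Mean over all unordered species pairs (the community-level TAPD)."""
    values = _require_complete(matrix, "mean pairwise distance")
    iu = np.triu_indices(matrix.n, k=1)
    return float(values[iu].mean())


def restrict_to_community(
    matrix: TraitDistanceMatrix,
    species: Iterable[str],
    scope: str | None = None,
) -> TraitDistanceMatrix:
    """Principal submatrix over a community's species, retagged with the
    community scope.  Pairwise distances are reused, not recomputed."""
    species = list(species)
    if len(set(species)) < 2:
        raise DegenerateInputError("community restriction requires >= 2 species")
    idx = matrix._index_of(species)
    sub = np.ix_(idx, idx)
    return TraitDistanceMatrix(
        [matrix.labels[i] for i in idx],
        matrix.values[sub].copy(),
        matrix.imputed[sub].copy(),
        scope if scope is not None else "community",
    )


def community_trait_matrix(
    table: pd.DataFrame,
    spec: TraitTypeSpec,
    species: Iterable[str],
    global_matrix: TraitDistanceMatrix | None = None,
    scope: str = "community",
    renormalize: bool = False,
) -> TraitDistanceMatrix:
    """Local trait distances for one community.

    Default: restrict the global matrix (ranges computed over the full
    pool).  ``renormalize=True`` recomputes Gower from scratch on the
    community's rows, re-normalising ranges within the community.
    """
    members = [s for s in species if s in set(map(str, table.index))]
    if renormalize or global_matrix is None:
        if len(members) < 2:
            raise DegenerateInputError("community has < 2 species with trait data")
        sub = gower_matrix(table.loc[members], spec)
        sub.scope = scope
        return impute_incomparable_pairs(sub)
    return restrict_to_community(global_matrix, members, scope)
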