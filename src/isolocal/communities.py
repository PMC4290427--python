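"""Survey records, route-level communities and the dataset-variant filters.

A "community" is the union of species recorded across all survey years on
one route, with abundance counts summed over years.  Three dataset variants
are analysed: FULL, NO_ALIENS (listed alien/invasive species removed) and
NO_RARE (species under a relative-abundance threshold removed).  The
richness filter (default: keep communities with at least 25 species) is
applied once, to FULL, before the variants are derived.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ConfigError, DataError, ValidationError

logger = logging.getLogger(__name__)

_COORD_TOL = 1e-6

VARIANTS = ("FULL", "NO_ALIENS", "NO_RARE")


@dataclass(frozen=True)
class SurveyRecord:
    """One species observation on one survey route (optionally one year)."""

    site: str
    species: str
    count: int
    year: Optional[int] = None
    lat: Optional[float] = None
    lon: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.site or not self.species:
            raise ValidationError("survey record needs non-empty site and species")
        if self.count < 0:
            raise ValidationError(f"negative count for {self.species} at {self.site}")


@dataclass
class FilterConfig:
    """Thresholds and auxiliary inputs for the community filters."""

    min_richness: int = 25
    rare_fraction: float = 0.01
    aliens: frozenset = frozenset()
    synonyms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_richness < 2:
            raise ConfigError("min_richness must be >= 2")
        if not 0.0 <= self.rare_fraction < 1.0:
            raise ConfigError("rare_fraction must be in [0, 1)")
        self.aliens = frozenset(self.aliens)


@dataclass
class CommunityTable:
    """Per-site species counts, with optional coordinates and a provenance
    tag naming the dataset variant."""

    counts: dict[str, dict[str, int]]
    coords: dict[str, Optional[tuple[float, float]]] = field(default_factory=dict)
    provenance: str = "FULL"

    def __post_init__(self) -> None:
        for site, spp in self.counts.items():
            if not spp:
                raise ValidationError(f"community {site!r} has no species")

    @property
    def sites(self) -> list[str]:
        return list(self.counts)

    def species(self, site: str) -> set[str]:
        return set(self.counts[site])

    def richness(self, site: str) -> int:
        return len(self.counts[site])

    @property
    def species_pool(self) -> set[str]:
        pool: set[str] = set()
        for spp in self.counts.values():
            pool |= set(spp)
        return pool

    def total_individuals(self) -> int:
        return sum(sum(spp.values()) for spp in self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site": site, "species": sp, "count": c}
            for site, spp in self.counts.items()
            for sp, c in sorted(spp.items())
        ]
        return pd.DataFrame(rows, columns=["site", "species", "count"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def read_survey_csv(path: str) -> list[SurveyRecord]:
    """Survey CSV with columns site,species,count[,year,lat,lon]."""
    records: list[SurveyRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"site", "species", "count"} <= set(
            reader.fieldnames
        ):
            raise DataError(f"{path}: expected columns site,species,count")
        for i, row in enumerate(reader, start=2):
            try:
                records.append(
                    SurveyRecord(
                        site=row["site"].strip(),
                        species=row["species"].strip(),
                        count=int(row["count"]),
                        year=int(row["year"]) if row.get("year") else None,
                        lat=float(row["lat"]) if row.get("lat") else None,
                        lon=float(row["lon"]) if row.get("lon") else None,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise DataError(f"{path} line {i}: {exc}") from exc
    if not records:
        raise DataError(f"{path}: no survey records")
    return records


def read_label_list(path: str) -> frozenset:
    """One label per line (used for alien/invasive species lists)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def read_synonym_map(path: str) -> dict[str, str]:
    """Two-column CSV mapping reported label -> accepted label."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ConfigError(f"{path}: synonym rows need two columns: {row}")
            out[row[0].strip()] = row[1].strip()
    return out


def collapse_years(records: Iterable[SurveyRecord]) -> CommunityTable:
    """Union species over years per site, summing counts.

    Coordinates must agree across a site's records (within a small
    tolerance); the collapsed community keeps one coordinate pair.
    """
    records = list(records)
    if not records:
        raise DataError("no survey records to collapse")
    counts: dict[str, dict[str, int]] = {}
    coords: dict[str, Optional[tuple[float, float]]] = {}
    for rec in records:
        site_counts = counts.setdefault(rec.site, {})
        site_counts[rec.species] = site_counts.get(rec.species, 0) + rec.count
        if rec.lat is not None and rec.lon is not None:
            prev = coords.get(rec.site)
            if prev is not None and (
                abs(prev[0] - rec.lat) > _COORD_TOL
                or abs(prev[1] - rec.lon) > _COORD_TOL
            ):
                raise DataError(
                    f"conflicting coordinates for site {rec.site!r}: "
                    f"{prev} vs {(rec.lat, rec.lon)}"
                )
            coords[rec.site] = (rec.lat, rec.lon)
        else:
            coords.setdefault(rec.site, None)
    return CommunityTable(counts, coords, provenance="FULL")


def filter_min_richness(table: CommunityTable, cfg: FilterConfig) -> CommunityTable:
    """Drop under-sampled communities with fewer than ``min_richness``
    species."""
    kept = {
        site: dict(spp)
        for site, spp in table.counts.items()
        if len(spp) >= cfg.min_richness
    }
    dropped = len(table.counts) - len(kept)
    if dropped:
        logger.info(
            "filter_min_richness: dropped %d of %d communities (< %d species)",
            dropped,
            len(table.counts),
            cfg.min_richness,
        )
    if not kept:
        logger.warning("filter_min_richness: no communities remain")
    coords = {s: table.coords.get(s) for s in kept}
    return CommunityTable(kept, coords, table.provenance)


def remove_aliens(table: CommunityTable, cfg: FilterConfig) -> CommunityTable:
    """Variant with listed alien/invasive species removed everywhere.

    The richness filter is *not* re-applied: the result is a variant of the
    same communities.  Communities emptied entirely are dropped (logged).
    """
    counts: dict[str, dict[str, int]] = {}
    removed = 0
    for site, spp in table.counts.items():
        kept = {sp: c for sp, c in spp.items() if sp not in cfg.aliens}
        removed += len(spp) - len(kept)
        if kept:
            counts[site] = kept
        else:
            logger.warning("remove_aliens: community %r emptied; dropped", site)
    if removed:
        logger.info("remove_aliens: removed %d species occurrences", removed)
    coords = {s: table.coords.get(s) for s in counts}
    return CommunityTable(counts, coords, provenance="NO_ALIENS")


def remove_rare(table: CommunityTable, cfg: FilterConfig) -> CommunityTable:
    """Variant with locally rare species removed.

    Within each community, species whose count is strictly less than
    ``rare_fraction`` of the community's total individuals are removed
    (strict "<": a species at exactly the threshold is kept).
    """
    counts: dict[str, dict[str, int]] = {}
    removed = 0
    for site, spp in table.counts.items():
        total = sum(spp.values())
        if total <= 0:
            raise DataError(f"community {site!r} has zero total count")
        kept = {
            sp: c for sp, c in spp.items() if c / total >= cfg.rare_fraction
        }
        removed += len(spp) - len(kept)
        if kept:
            counts[site] = kept
        else:  # pragma: no cover - cannot happen: the max species is never rare
            logger.warning("remove_rare: community %r emptied; dropped", site)
    if removed:
        logger.info("remove_rare: removed %d rare species occurrences", removed)
    coords = {s: table.coords.get(s) for s in counts}
    return CommunityTable(counts, coords, provenance="NO_RARE")


def _resolve_synonym(label: str, synonyms: Mapping[str, str]) -> str:
    seen = [label]
    while label in synonyms:
        label = synonyms[label]
        if label in seen:
            raise ConfigError(f"synonym cycle: {' -> '.join(seen + [label])}")
        seen.append(label)
    return label


def reconcile_names(
    table: CommunityTable, known: Iterable[str], cfg: FilterConfig
) -> CommunityTable:
    """Map survey names onto the phylogeny/trait label set.

    The synonym map (e.g. sub-species -> parent species) is applied first,
    merging counts; remaining labels not in ``known`` are dropped and
    logged with their total counts.
    """
    known = set(known)
    if not known:
        raise ValidationError("reconcile_names needs a non-empty known label set")
    counts: dict[str, dict[str, int]] = {}
    dropped: dict[str, int] = {}
    for site, spp in table.counts.items():
        merged: dict[str, int] = {}
        for sp, c in spp.items():
            target = _resolve_synonym(sp, cfg.synonyms)
            merged[target] = merged.get(target, 0) + c
        kept = {}
        for sp, c in merged.items():
            if sp in known:
                kept[sp] = c
            else:
                dropped[sp] = dropped.get(sp, 0) + c
        if kept:
            counts[site] = kept
        else:
            logger.warning("reconcile_names: community %r emptied; dropped", site)
    if dropped:
        logger.info(
            "reconcile_names: dropped %d unknown species (%d individuals): %s",
            len(dropped),
            sum(dropped.values()),
            ", ".join(sorted(dropped)[:10]),
        )
    coords = {s: table.coords.get(s) for s in counts}
    return CommunityTable(counts, coords, table.provenance)


def make_variants(
    table: CommunityTable, cfg: FilterConfig
) -> dict[str, CommunityTable]:
    """The three dataset variants, each derived independently from FULL."""
    return {
        "FULL": table,
        "NO_ALIENS": remove_aliens(table, cfg),
        "NO_RARE": remove_rare(table, cfg),
    }
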