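"""Fossil occurrence ingestion, deduplication, dating and 1-Myr binning.

An *occurrence* is one species recorded from one deposit with a
stratigraphic age interval (older/younger boundaries in Ma). The pipeline:

1. read the occurrence table (CSV/TSV) and validate ages;
2. deduplicate — one occurrence per species per geological stage (a species
   found in deposits of different stages keeps one occurrence per stage; a
   species found in several deposits of the same stage keeps the first);
3. date every occurrence by the midpoint of its age interval (this avoids
   systematically shifting species whose deposit spans two stages toward
   either boundary);
4. compile species counts into half-open 1-Myr bins ``[k, k+1)`` Ma indexed
   from the present (bin 0 = 0-1 Ma), per clade at each taxonomic rank.

Per-clade count vectors plus the clade's extant richness form the
:class:`CladeDataset` consumed by the Brownian-bridge model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timescale import GeoTimescale

logger = logging.getLogger(__name__)

__all__ = [
    "FossilOccurrence",
    "CladeDataset",
    "PlanEntry",
    "SchemaError",
    "RowError",
    "UnresolvableStageError",
    "EmptyCladeError",
    "HierarchyError",
    "RANKS",
    "read_occurrence_table",
    "mean_age",
    "deduplicate_occurrences",
    "bin_species_counts",
    "assemble_clade_dataset",
    "build_analysis_plan",
    "read_richness_table",
]

#: taxonomic ranks handled by the multi-rank analysis, lowest first
RANKS = ("family", "superfamily", "infraorder", "suborder")


class SchemaError(ValueError):
    """Input table lacks a mandatory column."""


class RowError(ValueError):
    """One or more rows violate the age-interval ordering."""


class UnresolvableStageError(ValueError):
    """Occurrence has no stage label and its age matches no timescale stage."""


class EmptyCladeError(ValueError):
    """A clade with zero occurrences cannot be analysed (no fossil anchor)."""


class HierarchyError(ValueError):
    """Rank labels are not hierarchically consistent."""


@dataclass(frozen=True)
class FossilOccurrence:
    """One species record from one deposit with an age interval."""

    species_name: str
    age_older: float
    age_younger: float
    deposit_id: str = ""
    stage_label: str | None = None
    family: str | None = None
    superfamily: str | None = None
    infraorder: str | None = None
    suborder: str | None = None

    def __post_init__(self):
        if not self.species_name:
            raise ValueError("species_name must be non-empty")
        if not (self.age_older >= self.age_younger >= 0):
            raise ValueError(
                f"require age_older >= age_younger >= 0, got "
                f"({self.age_older}, {self.age_younger}) for {self.species_name}"
            )

    def rank_label(self, rank: str) -> str | None:
        if rank == "order":
            return "order"
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return getattr(self, rank)


def mean_age(occ: FossilOccurrence) -> float:
    """Midpoint of the occurrence's age interval, in Ma."""
    return 0.5 * (occ.age_older + occ.age_younger)


# Column aliases accepted on input tables (lower-cased header -> field).
_COLUMN_ALIASES = {
    "species": "species_name",
    "species_name": "species_name",
    "taxon": "species_name",
    "family": "family",
    "superfamily": "superfamily",
    "super_family": "superfamily",
    "infraorder": "infraorder",
    "infra_order": "infraorder",
    "suborder": "suborder",
    "sub_order": "suborder",
    "deposit": "deposit_id",
    "deposit_id": "deposit_id",
    "locality": "deposit_id",
    "stage": "stage_label",
    "stage_label": "stage_label",
    "age_older": "age_older",
    "max_ma": "age_older",
    "older": "age_older",
    "age_younger": "age_younger",
    "min_ma": "age_younger",
    "younger": "age_younger",
}

_MANDATORY = ("species_name", "age_older", "age_younger")


def read_occurrence_table(source) -> list[FossilOccurrence]:
    """Read an occurrence table (CSV/TSV path, file-like, or DataFrame).

    Rows with missing or non-numeric ages are rejected with a logged
    warning naming the row index; rows with ``age_older < age_younger``
    raise :class:`RowError` listing every offending row.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    renames = {c: _COLUMN_ALIASES[c] for c in df.columns if c in _COLUMN_ALIASES}
    df = df.rename(columns=renames)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table missing mandatory columns: {missing}")

    df["age_older"] = pd.to_numeric(df["age_older"], errors="coerce")
    df["age_younger"] = pd.to_numeric(df["age_younger"], errors="coerce")

    bad_rows = df.index[df["age_older"].isna() | df["age_younger"].isna()].tolist()
    if bad_rows:
        logger.warning("rejected %d rows with missing/invalid ages: %s", len(bad_rows), bad_rows)
        df = df.drop(index=bad_rows)

    reversed_rows = df.index[df["age_older"] < df["age_younger"]].tolist()
    if reversed_rows:
        raise RowError(f"age_older < age_younger in rows {reversed_rows}")

    if df.empty:
        logger.warning("occurrence table contains no valid rows")
        return []

    def _opt(row, col):
        if col not in row or pd.isna(row[col]) or str(row[col]).strip() == "":
            return None
        return str(row[col]).strip()

    occs = []
    for _, row in df.iterrows():
        occs.append(
            FossilOccurrence(
                species_name=str(row["species_name"]).strip(),
                age_older=float(row["age_older"]),
                age_younger=float(row["age_younger"]),
                deposit_id=_opt(row, "deposit_id") or "",
                stage_label=_opt(row, "stage_label"),
                family=_opt(row, "family"),
                superfamily=_opt(row, "superfamily"),
                infraorder=_opt(row, "infraorder"),
                suborder=_opt(row, "suborder"),
            )
        )
    return occs


def _resolve_stage(occ: FossilOccurrence, ts: GeoTimescale) -> str:
    if occ.stage_label:
        return occ.stage_label
    try:
        return ts.stage_at(mean_age(occ)).name
    except Exception as exc:
        raise UnresolvableStageError(
            f"occurrence {occ.species_name!r} ({occ.age_older}-{occ.age_younger} Ma) "
            f"has no stage label and its age midpoint matches no timescale stage"
        ) from exc


def deduplicate_occurrences(
    occs: list[FossilOccurrence], ts: GeoTimescale
) -> list[FossilOccurrence]:
    """Keep one occurrence per (species, stage), preserving input order.

    A species found in deposits of different stages keeps one occurrence in
    each stage; deposits of similar age (same stage) collapse to the first.
    Idempotent.
    """
    seen: set[tuple[str, str]] = set()
    kept = []
    for occ in occs:
        key = (occ.species_name, _resolve_stage(occ, ts))
        if key not in seen:
            seen.add(key)
            kept.append(occ)
    return kept


def bin_species_counts(occs: list[FossilOccurrence]) -> np.ndarray:
    """Species counts per half-open 1-Myr bin ``[k, k+1)`` Ma.

    Entry ``k`` counts occurrences whose mean age falls in bin ``k``;
    vector length is ``ceil(max mean age) + 1`` (all-zero length-1 vector
    for empty input); the vector sums to the number of occurrences.
    """
    if not occs:
        return np.zeros(1, dtype=np.int64)
    ages = np.array([mean_age(o) for o in occs])
    length = int(math.ceil(ages.max())) + 1
    counts = np.zeros(length, dtype=np.int64)
    for k in np.floor(ages).astype(int):
        counts[k] += 1
    return counts


@dataclass
class CladeDataset:
    """Per-clade species counts on the 1-Myr grid plus extant richness.

    ``counts[k]`` is the number of (deduplicated) species occurrences with
    mean age in ``[k, k+1)`` Ma; ``extant_richness`` anchors the present-day
    end of the Brownian bridge (0 marks the clade extinct).
    """

    clade_name: str
    rank: str
    extant_richness: int
    counts: np.ndarray
    suborder: str | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.extant_richness < 0:
            raise ValueError("extant_richness must be >= 0")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise EmptyCladeError(f"clade {self.clade_name!r} has no binned occurrences")

    @property
    def is_extinct(self) -> bool:
        return self.extant_richness == 0

    @property
    def n_occurrences(self) -> int:
        return int(self.counts.sum())

    @property
    def oldest_bin(self) -> int:
        return int(np.nonzero(self.counts)[0][-1])

    @property
    def youngest_bin(self) -> int:
        return int(np.nonzero(self.counts)[0][0])


def read_richness_table(source) -> pd.DataFrame:
    """Read a clade richness table with columns (clade, rank, extant_species)."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    aliases = {"extant_richness": "extant_species", "richness": "extant_species",
               "clade_name": "clade", "name": "clade"}
    df = df.rename(columns={c: aliases[c] for c in df.columns if c in aliases})
    missing = [c for c in ("clade", "rank", "extant_species") if c not in df.columns]
    if missing:
        raise SchemaError(f"richness table missing columns: {missing}")
    return df


def _lookup_richness(richness: pd.DataFrame | None, clade: str, rank: str) -> int:
    if richness is None:
        return 0
    hit = richness[(richness["clade"] == clade) & (richness["rank"] == rank)]
    if hit.empty:
        return 0
    return int(hit["extant_species"].iloc[0])


def assemble_clade_dataset(
    occs: list[FossilOccurrence],
    clade_name: str,
    rank: str,
    richness: pd.DataFrame | None = None,
) -> CladeDataset:
    """Build the per-clade count vector and richness anchor at a given rank.

    ``rank="order"`` pools every occurrence (the order-level analysis uses
    the whole record). A clade absent from the richness table is treated as
    extinct. A clade with no occurrences raises :class:`EmptyCladeError`
    (the bridge needs at least one fossil anchor).
    """
    if rank == "order":
        members = list(occs)
    else:
        members = [o for o in occs if o.rank_label(rank) == clade_name]
    if not members:
        raise EmptyCladeError(f"no occurrences assigned to {rank} {clade_name!r}")
    counts = bin_species_counts(members)
    suborders = [o.suborder for o in members if o.suborder]
    suborder = suborders[0] if suborders else (clade_name if rank == "suborder" else None)
    return CladeDataset(
        clade_name=clade_name,
        rank=rank,
        extant_richness=_lookup_richness(richness, clade_name, rank),
        counts=counts,
        suborder=suborder,
    )


@dataclass(frozen=True)
class PlanEntry:
    """One analysis to run, or an alias pointing at a smaller-rank run."""

    clade: str
    rank: str
    action: str  # "run" | "alias"
    target_clade: str | None = None
    target_rank: str | None = None
    suborder: str | None = None


def _check_hierarchy(occs: list[FossilOccurrence]) -> None:
    for child_rank, parent_rank in zip(RANKS[:-1], RANKS[1:]):
        mapping: dict[str, str] = {}
        for o in occs:
            child, parent = o.rank_label(child_rank), o.rank_label(parent_rank)
            if child is None or parent is None:
                continue
            if mapping.setdefault(child, parent) != parent:
                raise HierarchyError(
                    f"{child_rank} {child!r} mapped to two {parent_rank}s: "
                    f"{mapping[child]!r} and {parent!r}"
                )


def build_analysis_plan(occs: list[FossilOccurrence]) -> list[PlanEntry]:
    """Decide which (clade, rank) pairs get their own run.

    A higher-rank group whose occurrences all belong to a single lower-rank
    group (a monotypic rank, e.g. a superfamily with one family) is not run
    twice: it becomes an alias to the smaller-rank run, whose posterior it
    reuses. Every clade with fossils appears exactly once, as a run or as an
    alias; aliases resolve transitively to a run.
    """
    _check_hierarchy(occs)
    entries: dict[tuple[str, str], PlanEntry] = {}
    resolved: dict[tuple[str, str], tuple[str, str]] = {}

    def _suborder_of(members: list[FossilOccurrence], clade: str, rank: str) -> str | None:
        subs = [o.suborder for o in members if o.suborder]
        if subs:
            return subs[0]
        return clade if rank == "suborder" else None

    for rank_idx, rank in enumerate(RANKS):
        groups: dict[str, list[FossilOccurrence]] = {}
        for o in occs:
            label = o.rank_label(rank)
            if label is not None:
                groups.setdefault(label, []).append(o)
        for clade in sorted(groups):
            members = groups[clade]
            alias_target = None
            # highest lower rank at which any member is labelled
            for lower in reversed(RANKS[:rank_idx]):
                labels = {o.rank_label(lower) for o in members}
                if labels == {None}:
                    continue
                if len(labels) == 1 and None not in labels:
                    (child,) = labels
                    alias_target = resolved.get((child, lower), (child, lower))
                break
            key = (clade, rank)
            if alias_target is not None:
                entries[key] = PlanEntry(
                    clade, rank, "alias",
                    target_clade=alias_target[0], target_rank=alias_target[1],
                    suborder=_suborder_of(members, clade, rank),
                )
                resolved[key] = alias_target
            else:
                entries[key] = PlanEntry(
                    clade, rank, "run", suborder=_suborder_of(members, clade, rank)
                )
                resolved[key] = key
    order = {r: i for i, r in enumerate(RANKS)}
    return sorted(entries.values(), key=lambda e: (order[e.rank], e.clade))
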