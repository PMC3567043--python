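"""Atlas tables: blocks, detection records, filters and occupancy outcomes.

A breeding-bird atlas surveys a fixed grid of blocks (~25 km² each) over a
multi-year period and records, per species and block, the strongest evidence
of breeding found: *possible*, *probable* or *confirmed*.  Two atlas periods
a couple of decades apart turn static occurrence into dynamics: a block
occupied in the first atlas either shows the species again in the second
(persistence) or does not (local extinction).  This module holds the table
model for those data, the breeding-confidence filters, the block validity
screen and the persistence/extinction classifier, plus strict CSV I/O.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Ordered breeding-confidence levels, weakest evidence first.
STATUS_ORDER: dict[str, int] = {"possible": 0, "probable": 1, "confirmed": 2}

BLOCKS_COLUMNS = ["block_id", "row", "col", "forest_pct"]
DETECTIONS_COLUMNS = ["block_id", "species", "atlas_period", "status"]


@dataclass(frozen=True)
class AtlasBlock:
    """One atlas block on the survey grid.

    Parameters
    ----------
    block_id : str
        Unique label.
    row, col : int
        0-based grid indices; the pair is unique within a region.
    forest_pct : float
        Percent forest cover in [0, 100].
    neighborhood_forest_pct : float, optional
        Mean cover of the block plus its eight grid neighbours, if computed.
    valid : bool
        Whether the block passes the validity screen (inside the region,
        not majority water).
    in_region : bool
        Whether the block footprint lies fully inside the study region.
    water_fraction : float
        Fraction of the block covered by water, in [0, 1].
    """

    block_id: str
    row: int
    col: int
    forest_pct: float
    neighborhood_forest_pct: float | None = None
    valid: bool = True
    in_region: bool = True
    water_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.forest_pct <= 100.0:
            raise ValidationError(
                f"forest_pct must be in [0, 100], got {self.forest_pct!r} "
                f"for block {self.block_id!r}"
            )
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValidationError("water_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DetectionRecord:
    """One species × block × atlas-period breeding-evidence record."""

    block_id: str
    species: str
    atlas_period: int
    status: str

    def __post_init__(self) -> None:
        if self.atlas_period not in (1, 2):
            raise ValidationError(f"atlas_period must be 1 or 2, got {self.atlas_period!r}")
        if self.status not in STATUS_ORDER:
            raise ValidationError(
                f"unknown breeding status {self.status!r}; "
                f"expected one of {sorted(STATUS_ORDER)}"
            )


@dataclass(frozen=True)
class OccupancyOutcome:
    """Persistence/extinction outcome for a block occupied in atlas 1.

    ``persisted + extinct == 1`` always; outcomes exist only for blocks
    where the species was present in the first atlas.
    """

    block_id: str
    species: str
    persisted: int
    extinct: int
    covariate_x: float

    def __post_init__(self) -> None:
        if self.persisted + self.extinct != 1 or self.persisted not in (0, 1):
            raise ValidationError("persisted and extinct must be complementary 0/1 flags")


def deduplicate_records(records: Iterable[DetectionRecord]) -> list[DetectionRecord]:
    """Keep the highest-confidence status per (block, species, period).

    Atlas protocols upgrade breeding codes as stronger evidence accumulates,
    so the strongest record is the block's status for the period.
    """
    best: dict[tuple[str, str, int], DetectionRecord] = {}
    for rec in records:
        key = (rec.block_id, rec.species, rec.atlas_period)
        cur = best.get(key)
        if cur is None or STATUS_ORDER[rec.status] > STATUS_ORDER[cur.status]:
            best[key] = rec
    return list(best.values())


def apply_confidence_filter(
    records: Iterable[DetectionRecord], mode: str = "any_evidence"
) -> set[tuple[str, str, int]]:
    """Reduce detection records to a presence set under a confidence rule.

    Parameters
    ----------
    records : iterable of DetectionRecord
        Deduplicated detection records.
    mode : {"any_evidence", "confirmed_only"}
        ``any_evidence`` counts a species present under any breeding code;
        ``confirmed_only`` restricts presence to confirmed breeding (the
        conservative sensitivity scenario).

    Returns
    -------
    set of (block_id, species, atlas_period)
        Keys judged present under the rule.
    """
    if mode not in ("any_evidence", "confirmed_only"):
        raise ValidationError(f"unknown confidence mode {mode!r}")
    present: set[tuple[str, str, int]] = set()
    for rec in records:
        if rec.status not in STATUS_ORDER:  # pragma: no cover - guarded in ctor
            raise ValidationError(f"unknown breeding status {rec.status!r}")
        if mode == "any_evidence" or rec.status == "confirmed":
            present.add((rec.block_id, rec.species, rec.atlas_period))
    return present


def classify_outcomes(
    presence: set[tuple[str, str, int]],
    species: str,
    blocks: Iterable[AtlasBlock],
    covariate: str = "block",
) -> list[OccupancyOutcome]:
    """Classify per-block persistence/extinction for one species.

    A block enters the conditioning set only if the species was present
    there in atlas period 1; it persisted if also present in period 2 and
    went locally extinct otherwise.  Only valid blocks are considered.

    Parameters
    ----------
    covariate : {"block", "neighborhood"}
        Which forest-cover covariate to attach: the block's own percent
        cover, or the mean over the block plus its eight neighbours.
    """
    if covariate not in ("block", "neighborhood"):
        raise ValidationError(f"unknown covariate scale {covariate!r}")
    outcomes: list[OccupancyOutcome] = []
    for blk in blocks:
        if not blk.valid:
            continue
        if (blk.block_id, species, 1) not in presence:
            continue
        if covariate == "neighborhood":
            if blk.neighborhood_forest_pct is None:
                raise ValidationError(
                    f"block {blk.block_id!r} has no neighborhood_forest_pct"
                )
            x = blk.neighborhood_forest_pct
        else:
            x = blk.forest_pct
        persisted = int((blk.block_id, species, 2) in presence)
        outcomes.append(
            OccupancyOutcome(
                block_id=blk.block_id,
                species=species,
                persisted=persisted,
                extinct=1 - persisted,
                covariate_x=x,
            )
        )
    return outcomes


def exclude_invalid_blocks(
    blocks: Iterable[AtlasBlock],
    require_in_region: bool = True,
    max_water_fraction: float = 0.5,
) -> list[AtlasBlock]:
    """Drop blocks outside the region or majority-covered by water.

    Mirrors the usual atlas screen: blocks whose footprint crosses the
    region boundary do not align with the land-cover data, and majority-water
    blocks have no meaningful forest percentage.  Removals are logged.
    """
    kept: list[AtlasBlock] = []
    removed = 0
    for blk in blocks:
        ok = blk.valid
        if require_in_region and not blk.in_region:
            ok = False
        if blk.water_fraction > max_water_fraction:
            ok = False
        if ok:
            kept.append(replace(blk, valid=True))
        else:
            removed += 1
    logger.info("exclude_invalid_blocks: removed %d block(s), kept %d", removed, len(kept))
    return kept


# ---------------------------------------------------------------------------
# CSV I/O (strict headers, UTF-8)
# ---------------------------------------------------------------------------

def blocks_to_frame(blocks: Iterable[AtlasBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.block_id, b.row, b.col, b.forest_pct) for b in blocks],
        columns=BLOCKS_COLUMNS,
    )


def write_blocks(blocks: Iterable[AtlasBlock], path) -> None:
    blocks_to_frame(blocks).to_csv(path, index=False, encoding="utf-8")


def read_blocks(path) -> list[AtlasBlock]:
    df = pd.read_csv(path, encoding="utf-8")
    if list(df.columns) != BLOCKS_COLUMNS:
        raise ValidationError(
            f"blocks table must have columns {BLOCKS_COLUMNS}, got {list(df.columns)}"
        )
    return [
        AtlasBlock(block_id=str(r.block_id), row=int(r.row), col=int(r.col),
                   forest_pct=float(r.forest_pct))
        for r in df.itertuples(index=False)
    ]


def detections_to_frame(records: Iterable[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.block_id, r.species, r.atlas_period, r.status) for r in records],
        columns=DETECTIONS_COLUMNS,
    )


def write_detections(records: Iterable[DetectionRecord], path) -> None:
    detections_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_detections(path) -> list[DetectionRecord]:
    df = pd.read_csv(path, encoding="utf-8")
    if list(df.columns) != DETECTIONS_COLUMNS:
        raise ValidationError(
            f"detections table must have columns {DETECTIONS_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    return [
        DetectionRecord(block_id=str(r.block_id), species=str(r.species),
                        atlas_period=int(r.atlas_period), status=str(r.status))
        for r in df.itertuples(index=False)
    ]
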