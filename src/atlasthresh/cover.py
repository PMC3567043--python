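"""Percent forest cover from a categorical land-cover grid.

Forest percent per block is the fraction of grid cells in any of the three
forest classes (deciduous, coniferous, mixed) within the block footprint,
computed from a class-frequency histogram of the footprint.  Unclassified or
non-forest cells stay in the denominator, so the percentage is relative to
the whole block.  The landscape-scale covariate is the arithmetic mean cover
of a focal block plus its (up to eight) existing grid neighbours; edge and
corner blocks average over however many neighbours exist — no padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .atlas import AtlasBlock
from .errors import BoundsError, ValidationError

__all__ = [
    "FOREST_CLASSES",
    "LandCoverGrid",
    "class_histogram",
    "block_forest_percent",
    "neighborhood_forest_percent",
    "read_ascii_grid",
    "read_raster",
]

#: Land-cover class names whose cells count as forest.
FOREST_CLASSES = frozenset({"deciduous_forest", "coniferous_forest", "mixed_forest"})

#: Footprint: half-open cell range (row_start, row_stop, col_start, col_stop).
Footprint = tuple[int, int, int, int]


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster with a code → class-name map."""

    cells: np.ndarray
    class_map: Mapping[int, str]
    cell_size: float = 30.0  # informational, length units per cell edge

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2 or self.cells.size == 0:
            raise ValidationError("cells must be a non-empty 2-D array")
        if not np.issubdtype(self.cells.dtype, np.integer):
            raise ValidationError("cells must hold integer class codes")
        present = set(np.unique(self.cells).tolist())
        missing = present - set(self.class_map)
        if missing:
            raise ValidationError(f"class codes missing from class_map: {sorted(missing)}")


def _footprint_view(grid: LandCoverGrid, footprint: Footprint) -> np.ndarray:
    r0, r1, c0, c1 = footprint
    nrows, ncols = grid.cells.shape
    if r0 >= r1 or c0 >= c1:
        raise ValidationError(f"empty footprint {footprint!r}")
    if r0 < 0 or c0 < 0 or r1 > nrows or c1 > ncols:
        raise BoundsError(f"footprint {footprint!r} outside {nrows}x{ncols} grid")
    return grid.cells[r0:r1, c0:c1]


def class_histogram(grid: LandCoverGrid, footprint: Footprint) -> dict[int, int]:
    """Frequency histogram of class codes within a footprint.

    Counts sum to the footprint size.
    """
    view = _footprint_view(grid, footprint)
    codes, counts = np.unique(view, return_counts=True)
    return {int(c): int(n) for c, n in zip(codes, counts)}


def block_forest_percent(grid: LandCoverGrid, footprint: Footprint) -> float:
    """Percent of footprint cells in the three forest classes, in [0, 100]."""
    hist = class_histogram(grid, footprint)
    total = sum(hist.values())
    forest = sum(n for code, n in hist.items() if grid.class_map[code] in FOREST_CLASSES)
    return 100.0 * forest / total


def neighborhood_forest_percent(blocks: Iterable[AtlasBlock], focal: str) -> float:
    """Mean forest percent over a focal block plus its 3×3 grid neighbours.

    Neighbours are resolved by (row, col) adjacency; blocks missing from the
    region (edges, corners, gaps) simply do not contribute.
    """
    by_pos: dict[tuple[int, int], AtlasBlock] = {}
    focal_blk: AtlasBlock | None = None
    for blk in blocks:
        by_pos[(blk.row, blk.col)] = blk
        if blk.block_id == focal:
            focal_blk = blk
    if focal_blk is None:
        raise ValidationError(f"focal block {focal!r} not found")
    vals = [
        by_pos[(focal_blk.row + dr, focal_blk.col + dc)].forest_pct
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (focal_blk.row + dr, focal_blk.col + dc) in by_pos
    ]
    return float(np.mean(vals))


def attach_neighborhood_cover(blocks: list[AtlasBlock]) -> list[AtlasBlock]:
    """Return blocks with ``neighborhood_forest_pct`` filled in."""
    from dataclasses import replace

    out = []
    for blk in blocks:
        out.append(
            replace(blk, neighborhood_forest_pct=neighborhood_forest_percent(blocks, blk.block_id))
        )
    return out


# ---------------------------------------------------------------------------
# Raster readers
# ---------------------------------------------------------------------------

def read_ascii_grid(path) -> np.ndarray:
    """Read an ESRI ASCII grid (.asc) of integer class codes."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise ValidationError(f"{path} is not an ESRI ASCII grid (missing ncols/nrows)")
    data = np.loadtxt(lines[n_header:], dtype=int)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValidationError(
            f"grid shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return data


def read_raster(path) -> np.ndarray:
    """Read a land-cover raster (.asc ESRI ASCII, or .tif via tifffile)."""
    path = Path(path)
    if path.suffix.lower() in {".asc", ".txt"}:
        return read_ascii_grid(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return np.asarray(tifffile.imread(path))
    raise ValidationError(f"unsupported raster format: {path.suffix!r}")
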