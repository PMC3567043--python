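"""Synthetic atlas landscapes and species dynamics with known thresholds.

The generator emulates two study-region archetypes.  A Vermont-like region
has few blocks (175 priority blocks) with homogeneously high forest cover
(mean ≈ 73.9 %); a New-York-like region has many blocks (~5074) with a much
wider, left-heavy cover distribution (mean ≈ 63.1 %, many low-cover blocks).
Cover is drawn i.i.d. per block from a Beta distribution rescaled to
[0, 100], parameterised by its mean and a concentration (a Beta(mκ, (1−m)κ)
with m the mean as a proportion): two parameters suffice to reproduce a
narrow high-cover hump versus a broad left-tailed spread.

Species dynamics follow the forward model that the fitting stage assumes:
a block is occupied in atlas 1 with fixed probability (independent of cover
by default), and an occupied block persists into atlas 2 with probability

    p(x) = expit(b0 + b1·x + b2·max(0, x − ψ))

where x is percent forest cover and ψ the true breakpoint; b2 = 0 encodes a
non-threshold species.  Breeding-confidence codes are drawn from a fixed
mix.  Every species gets its own RNG stream derived from (species, seed),
so adding a species never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .atlas import AtlasBlock, DetectionRecord
from .errors import GridCapacityError, ValidationError

__all__ = [
    "RegionProfile",
    "SpeciesResponseSpec",
    "VT_LIKE",
    "NY_LIKE",
    "generate_landscape",
    "simulate_species_dynamics",
]


@dataclass(frozen=True)
class RegionProfile:
    """Parametric description of a study region's block grid and cover.

    Parameters
    ----------
    name : str
        Region label, used in block ids.
    n_blocks : int
        Number of atlas blocks to generate.
    grid_dims : (int, int)
        Grid rows × cols; must hold at least ``n_blocks``.
    cover_mean : float
        Mean percent forest cover of the Beta cover distribution.
    cover_concentration : float
        Beta concentration κ; larger κ means tighter spread around the mean
        (var = m(1−m)/(κ+1) on the proportion scale).
    """

    name: str
    n_blocks: int
    grid_dims: tuple[int, int]
    cover_mean: float
    cover_concentration: float

    def __post_init__(self) -> None:
        rows, cols = self.grid_dims
        if self.n_blocks < 0:
            raise ValidationError("n_blocks must be >= 0")
        if rows < 1 or cols < 1:
            raise ValidationError("grid_dims must be at least 1x1")
        if not 0.0 < self.cover_mean < 100.0:
            raise ValidationError("cover_mean must be in (0, 100)")
        if self.cover_concentration <= 0:
            raise ValidationError("cover_concentration must be positive")


#: Vermont-like preset: 175 priority blocks, homogeneous high cover.
VT_LIKE = RegionProfile(
    name="vt", n_blocks=175, grid_dims=(15, 12),
    cover_mean=73.89, cover_concentration=12.0,
)

#: New-York-like preset: ~5074 blocks, wide left-heavy cover spread.
NY_LIKE = RegionProfile(
    name="ny", n_blocks=5074, grid_dims=(72, 71),
    cover_mean=63.10, cover_concentration=3.5,
)


@dataclass(frozen=True)
class SpeciesResponseSpec:
    """True piecewise-logistic response of one synthetic species.

    ``slope_change == 0`` reduces the persistence curve to an ordinary
    logistic in cover (a non-threshold species).
    """

    species_code: str
    psi_true: float
    intercept: float
    slope_below: float
    slope_change: float
    occupancy1_prob: float = 1.0
    confidence_mix: tuple[float, float, float] = (0.3, 0.3, 0.4)

    def __post_init__(self) -> None:
        if not 0.0 < self.psi_true < 100.0:
            raise ValidationError("psi_true must be in (0, 100)")
        if not 0.0 <= self.occupancy1_prob <= 1.0:
            raise ValidationError("occupancy1_prob must be in [0, 1]")
        mix = np.asarray(self.confidence_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise ValidationError(
                "confidence_mix must be three non-negative probabilities summing to 1"
            )

    def persistence_prob(self, x) -> np.ndarray:
        """Closed-form persistence probability at percent cover ``x``."""
        x = np.asarray(x, dtype=float)
        eta = (
            self.intercept
            + self.slope_below * x
            + self.slope_change * np.maximum(0.0, x - self.psi_true)
        )
        return expit(eta)


def generate_landscape(profile: RegionProfile, seed: int) -> list[AtlasBlock]:
    """Draw a block grid with i.i.d. Beta-distributed forest cover.

    Blocks fill the grid row-major.  Identical (profile, seed) pairs give
    identical output.
    """
    rows, cols = profile.grid_dims
    if profile.n_blocks > rows * cols:
        raise GridCapacityError(
            f"{profile.n_blocks} blocks do not fit a {rows}x{cols} grid"
        )
    rng = np.random.default_rng(seed)
    m = profile.cover_mean / 100.0
    kappa = profile.cover_concentration
    covers = 100.0 * rng.beta(m * kappa, (1.0 - m) * kappa, size=profile.n_blocks)
    # beta() is open on (0,1) but guard the block invariant anyway
    covers = np.clip(covers, 0.0, 100.0)
    return [
        AtlasBlock(
            block_id=f"{profile.name}-{i:05d}",
            row=i // cols,
            col=i % cols,
            forest_pct=float(covers[i]),
        )
        for i in range(profile.n_blocks)
    ]


_STATUSES = ("possible", "probable", "confirmed")


def _species_rng(species_code: str, seed: int) -> np.random.Generator:
    # one stream per (species, seed): adding species never shifts other draws
    return np.random.default_rng([zlib.crc32(species_code.encode("utf-8")), seed])


def simulate_species_dynamics(
    blocks: list[AtlasBlock], spec: SpeciesResponseSpec, seed: int
) -> list[DetectionRecord]:
    """Simulate two-atlas detection records for one species.

    Each block is occupied in atlas 1 with ``occupancy1_prob``; occupied
    blocks persist into atlas 2 with the piecewise-logistic probability at
    the block's cover.  One record is emitted per occupied block and period,
    with a breeding-confidence code drawn from ``confidence_mix``.
    """
    if not blocks:
        raise ValidationError("blocks must be nonempty")
    rng = _species_rng(spec.species_code, seed)
    records: list[DetectionRecord] = []
    for blk in blocks:
        if rng.random() >= spec.occupancy1_prob:
            continue
        status1 = _STATUSES[rng.choice(3, p=spec.confidence_mix)]
        records.append(DetectionRecord(blk.block_id, spec.species_code, 1, status1))
        p = float(spec.persistence_prob(blk.forest_pct))
        if rng.random() < p:
            status2 = _STATUSES[rng.choice(3, p=spec.confidence_mix)]
            records.append(DetectionRecord(blk.block_id, spec.species_code, 2, status2))
    return records
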