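"""Tile-selection policies: random and systematic random sampling.

Random sampling (RS) draws ``n_T`` tiles uniformly without replacement from
the usable foreground tiles.  Systematic random sampling (SRS) overlays the
tile grid with square *sample grids* of ``g x g`` tiles, anchored at the
slide origin, and draws one tile uniformly from each; draws that land on
background or artifact tiles are discarded without replacement, so the
realized sample size ``n_T`` is at most the number of blocks.  SRS spreads
the sample evenly across the slide, which lowers the variance of spatial
averages whenever nearby tiles are positively correlated — the usual
situation in tissue.

The block side ``g`` is set from a nominal sample size ``n_nom``, the
foreground tile count ``n_F`` and the non-artifact fraction γ:
``g = floor(sqrt(gamma * n_F / n_nom))`` — a slide with γ·n_F usable tiles
cut into g²-tile blocks yields about γ·n_F/g² ≈ n_nom draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import TileGrid

POLICIES = ("rs", "srs", "exhaustive")


def grid_dimension(gamma: float, n_F: int, n_nom: int) -> int:
    """Sample-grid side length in tiles for a nominal SRS sample size.

    ``g = floor(sqrt(gamma * n_F / n_nom))``, clamped to at least 1 (at
    ``g = 1`` SRS degenerates to exhaustive tiling).
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0, 1], got {gamma}")
    if n_F < 1:
        raise ValueError(f"n_F must be >= 1, got {n_F}")
    if n_nom < 1:
        raise ValueError(f"n_nom must be >= 1, got {n_nom}")
    return max(1, math.floor(math.sqrt(gamma * n_F / n_nom)))


@dataclass(frozen=True)
class SamplingPlan:
    """How to select tiles from one slide.

    ``policy`` is one of ``"rs"``, ``"srs"``, ``"exhaustive"``.  For RS,
    ``n_nom`` is the sample size drawn.  For SRS, ``g`` is used when given,
    otherwise derived from ``(gamma, n_F, n_nom)`` at sampling time.
    """

    policy: str
    n_nom: int | None = None
    g: int | None = None
    gamma: float = 1.0
    seed: int | Sequence[int] = 0

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"policy must be one of {POLICIES}, got {self.policy!r}")
        if self.n_nom is not None and self.n_nom < 1:
            raise ValueError("n_nom must be >= 1")
        if self.g is not None and self.g < 1:
            raise ValueError("g must be >= 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.policy == "rs" and self.n_nom is None:
            raise ValueError("RS requires n_nom")
        if self.policy == "srs" and self.n_nom is None and self.g is None:
            raise ValueError("SRS requires n_nom or g")


@dataclass(frozen=True)
class SampleSet:
    """Tiles chosen by one sampling run: unique, foreground, non-artifact."""

    tiles: tuple[tuple[int, int], ...]
    plan: SamplingPlan

    def __post_init__(self) -> None:
        tiles = tuple((int(r), int(c)) for r, c in self.tiles)
        if len(set(tiles)) != len(tiles):
            raise ValueError("sampled tiles must be unique")
        object.__setattr__(self, "tiles", tiles)

    @property
    def n_T(self) -> int:
        """Actual (realized) sample size."""
        return len(self.tiles)


def exhaustive_sample(grid: TileGrid, plan: SamplingPlan | None = None) -> SampleSet:
    """All usable foreground tiles, row-major — the no-sampling baseline."""
    if plan is None:
        plan = SamplingPlan(policy="exhaustive")
    return SampleSet(tuple(grid.usable_tiles()), plan)


def random_sample(grid: TileGrid, n_T: int, seed: int | Sequence[int] = 0) -> SampleSet:
    """RS: ``n_T`` tiles uniform without replacement from the usable pool."""
    pool = grid.usable_tiles()
    if not 1 <= n_T <= len(pool):
        raise ValueError(
            f"n_T must be in [1, {len(pool)}] (usable foreground tiles), got {n_T}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pool), size=n_T, replace=False))
    plan = SamplingPlan(policy="rs", n_nom=n_T, seed=seed)
    return SampleSet(tuple(pool[i] for i in idx), plan)


def systematic_random_sample(
    grid: TileGrid, g: int, seed: int | Sequence[int] = 0
) -> SampleSet:
    """SRS: one uniform draw per ``g x g`` block; unusable draws discarded.

    Blocks are anchored at tile (0, 0); edge blocks may be smaller.  A draw
    that lands on a background or artifact tile is ignored (no re-draw), so
    ``n_T`` can fall below the block count.  With ``g = 1`` every usable tile
    is its own block and the result equals :func:`exhaustive_sample`.
    """
    if g < 1:
        raise ValueError(f"g must be >= 1, got {g}")
    rng = np.random.default_rng(seed)
    usable = grid.usable
    tiles: list[tuple[int, int]] = []
    for r0 in range(0, grid.n_rows, g):
        for c0 in range(0, grid.n_cols, g):
            r = r0 + rng.integers(min(g, grid.n_rows - r0))
            c = c0 + rng.integers(min(g, grid.n_cols - c0))
            if usable[r, c]:
                tiles.append((int(r), int(c)))
    plan = SamplingPlan(policy="srs", g=g, seed=seed)
    return SampleSet(tuple(tiles), plan)


def draw_sample(grid: TileGrid, plan: SamplingPlan) -> SampleSet:
    """Dispatch a :class:`SamplingPlan` to the matching policy."""
    if plan.policy == "exhaustive":
        return exhaustive_sample(grid, plan)
    if plan.policy == "rs":
        assert plan.n_nom is not None
        return random_sample(grid, plan.n_nom, seed=plan.seed)
    g = plan.g
    if g is None:
        assert plan.n_nom is not None
        g = grid_dimension(plan.gamma, grid.n_F, plan.n_nom)
    return systematic_random_sample(grid, g, seed=plan.seed)
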