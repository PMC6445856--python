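"""Foreground segmentation, tiling, and artifact bookkeeping.

A whole-slide image is reduced to a :class:`TileGrid`: a row-major grid of
fixed-size square tiles (default 500 px at ~0.5 µm/px, i.e. 250 µm on a
side), each labeled background, foreground (tissue) or artifact.  Foreground
status comes from a local-entropy tissue mask; the *artifact* flag marks
foreground tiles spoiled by gray scanner/coverslip artifacts and is a
refinement of foreground — ``n_F`` counts all tissue tiles, artifact or not,
while sampling draws only from the usable (non-artifact) ones.

The non-artifact fraction γ = usable/foreground is estimated by probing a
random subset of foreground tiles, exactly as one would on a real slide
where running the detector on every tile is what sampling avoids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from skimage import morphology
from skimage.filters import threshold_otsu
from skimage.filters.rank import entropy as _rank_entropy
from skimage.util import img_as_ubyte

from .profiling import DEFAULT_MICRONS_PER_PX, DEFAULT_PATCH_SIZE_PX

BACKGROUND, FOREGROUND, ARTIFACT = 0, 1, 2

_STATUS_NAMES = {BACKGROUND: "background", FOREGROUND: "foreground", ARTIFACT: "artifact"}


@dataclass(frozen=True)
class ForegroundMask:
    """Binary tissue mask aligned to the source image."""

    mask: np.ndarray
    provenance: str = "computed"  # {"computed", "loaded"}

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        object.__setattr__(self, "mask", m)


def compute_entropy_mask(
    image: np.ndarray,
    window_px: int = 15,
    cleanup_radius_px: int = 2,
) -> ForegroundMask:
    """Segment tissue from background by local-entropy thresholding.

    Local intensity entropy is computed in a ``window_px`` square around each
    pixel; tissue is textured and has high entropy, empty glass is nearly
    constant and has low entropy.  The threshold between the two is chosen
    automatically by Otsu's criterion on the entropy image, and small
    components are removed by a morphological opening of radius
    ``cleanup_radius_px``.  Because entropy depends only on the shape of the
    local histogram, the mask is invariant to adding a constant to all
    intensities.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale or RGB")
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError(f"window_px must be odd and >= 3, got {window_px}")
    if min(img.shape) < window_px:
        raise ValueError(
            f"image {img.shape} is smaller than the entropy window ({window_px} px)"
        )
    if img.dtype != np.uint8:
        lo, hi = float(img.min()), float(img.max())
        if hi > lo:
            img = (img - lo) / (hi - lo)
        else:
            img = np.zeros_like(img, dtype=float)
        img = img_as_ubyte(img)
    ent = _rank_entropy(img, np.ones((window_px, window_px), dtype=bool))
    if np.ptp(ent) == 0:  # e.g. constant image: zero entropy everywhere
        return ForegroundMask(np.zeros(img.shape, dtype=bool))
    mask = ent > threshold_otsu(ent)
    if cleanup_radius_px > 0:
        mask = morphology.opening(mask, morphology.disk(cleanup_radius_px))
    return ForegroundMask(mask)


@dataclass
class TileGrid:
    """Tiling of a slide with per-tile status.

    Tiles are 0-based and row-major; tile ``(r, c)`` covers the half-open
    pixel box ``[r*P, (r+1)*P) x [c*P, (c+1)*P)`` with ``P = patch_size_px``.
    ``tissue`` marks foreground tiles; ``artifact`` (a subset of ``tissue``)
    marks foreground tiles spoiled by gray artifacts.
    """

    tissue: np.ndarray
    artifact: np.ndarray | None = None
    patch_size_px: int = DEFAULT_PATCH_SIZE_PX
    microns_per_px: float = DEFAULT_MICRONS_PER_PX

    def __post_init__(self) -> None:
        self.tissue = np.asarray(self.tissue, dtype=bool)
        if self.tissue.ndim != 2:
            raise ValueError("tissue must be a 2-D tile raster")
        if self.artifact is None:
            self.artifact = np.zeros_like(self.tissue)
        else:
            self.artifact = np.asarray(self.artifact, dtype=bool)
        if self.artifact.shape != self.tissue.shape:
            raise ValueError("artifact grid must match tissue grid shape")
        if np.any(self.artifact & ~self.tissue):
            raise ValueError("artifact tiles must be foreground tiles")
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")

    @property
    def n_rows(self) -> int:
        return self.tissue.shape[0]

    @property
    def n_cols(self) -> int:
        return self.tissue.shape[1]

    @property
    def n_F(self) -> int:
        """Number of foreground (tissue) tiles, artifact tiles included."""
        return int(self.tissue.sum())

    @property
    def n_artifact(self) -> int:
        return int(self.artifact.sum())

    @property
    def n_usable(self) -> int:
        """Foreground tiles that are not artifacts — the sampling pool."""
        return self.n_F - self.n_artifact

    @property
    def usable(self) -> np.ndarray:
        return self.tissue & ~self.artifact

    @property
    def status(self) -> np.ndarray:
        """Per-tile label grid: background / foreground / artifact."""
        s = np.where(self.tissue, FOREGROUND, BACKGROUND)
        s[self.artifact] = ARTIFACT
        return s.astype(np.int8)

    def tiles_where(self, mask: np.ndarray) -> list[tuple[int, int]]:
        """Row-major list of (row, col) for tiles where ``mask`` is true."""
        rows, cols = np.nonzero(mask)
        return list(zip(rows.tolist(), cols.tolist()))

    def usable_tiles(self) -> list[tuple[int, int]]:
        return self.tiles_where(self.usable)

    def foreground_tiles(self) -> list[tuple[int, int]]:
        return self.tiles_where(self.tissue)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "patch_size_px": self.patch_size_px,
                "microns_per_px": self.microns_per_px,
                "tissue": self.tissue.astype(int).tolist(),
                "artifact": self.artifact.astype(int).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        d = json.loads(text)
        return cls(
            tissue=np.asarray(d["tissue"], dtype=bool),
            artifact=np.asarray(d["artifact"], dtype=bool),
            patch_size_px=int(d["patch_size_px"]),
            microns_per_px=float(d["microns_per_px"]),
        )


def tile_and_classify(
    mask: ForegroundMask | np.ndarray,
    patch_size_px: int = DEFAULT_PATCH_SIZE_PX,
    foreground_overlap_threshold: float = 0.5,
    microns_per_px: float = DEFAULT_MICRONS_PER_PX,
) -> TileGrid:
    """Tile a foreground mask and classify tiles by mask overlap.

    A tile is foreground iff the fraction of its pixels inside the mask is at
    least ``foreground_overlap_threshold``.  Partial tiles at the right and
    bottom edges (narrower than ``patch_size_px``) are dropped.
    """
    if not 0.0 < foreground_overlap_threshold <= 1.0:
        raise ValueError("foreground_overlap_threshold must be in (0, 1]")
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    P = int(patch_size_px)
    if P <= 0:
        raise ValueError("patch_size_px must be positive")
    n_rows, n_cols = m.shape[0] // P, m.shape[1] // P
    if n_rows == 0 or n_cols == 0:
        return TileGrid(
            np.zeros((0, 0), dtype=bool),
            patch_size_px=P,
            microns_per_px=microns_per_px,
        )
    cropped = m[: n_rows * P, : n_cols * P]
    frac = cropped.reshape(n_rows, P, n_cols, P).mean(axis=(1, 3))
    tissue = frac >= foreground_overlap_threshold
    return TileGrid(tissue, patch_size_px=P, microns_per_px=microns_per_px)


def detect_gray_artifact(
    patch: np.ndarray,
    saturation_threshold: float = 20.0,
    intensity_band: tuple[float, float] = (60.0, 200.0),
) -> bool:
    """True iff an RGB patch looks like a gray scanner/coverslip artifact.

    Gray artifacts are nearly unsaturated (small per-pixel channel spread) at
    mid-gray intensity; white background is also unsaturated but too bright,
    and stained tissue is saturated.  Thresholds are in 8-bit intensity units.
    """
    p = np.asarray(patch, dtype=float)
    if p.ndim != 3 or p.shape[2] != 3:
        raise ValueError("patch must be an RGB raster of shape (H, W, 3)")
    spread = p.max(axis=2) - p.min(axis=2)
    mean_saturation = float(spread.mean())
    mean_intensity = float(p.mean())
    lo, hi = intensity_band
    return mean_saturation < saturation_threshold and lo <= mean_intensity <= hi


def estimate_gamma(
    grid: TileGrid,
    n_probe: int,
    seed: int | Sequence[int] = 0,
    patch_source: Callable[[int, int], np.ndarray] | None = None,
    detector: Callable[[np.ndarray], bool] = detect_gray_artifact,
) -> float:
    """Estimate γ, the non-artifact fraction of foreground tiles, by probing.

    ``n_probe`` foreground tiles are sampled uniformly without replacement;
    each is checked for artifacts — against the grid's artifact flags, or by
    running ``detector`` on ``patch_source(row, col)`` when a pixel source is
    supplied — and γ̂ = 1 − (artifact probes)/n_probe.  The estimator is
    unbiased with binomial standard error √(γ(1−γ)/n_probe).
    """
    if grid.n_F == 0:
        raise ValueError("cannot estimate gamma on a slide with no foreground tiles")
    if not 1 <= n_probe <= grid.n_F:
        raise ValueError(f"n_probe must be in [1, n_F={grid.n_F}], got {n_probe}")
    rng = np.random.default_rng(seed)
    pool = grid.foreground_tiles()
    idx = rng.choice(len(pool), size=n_probe, replace=False)
    n_art = 0
    for i in idx:
        r, c = pool[i]
        if patch_source is not None:
            n_art += bool(detector(patch_source(r, c)))
        else:
            n_art += bool(grid.artifact[r, c])
    return 1.0 - n_art / n_probe
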