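"""Synthetic slide cohorts: spatially correlated cell-count simulation.

Everything downstream of segmentation — sampling policies, profiles, batch
reproducibility, clinical associations — can be exercised on cohorts built
here, with no slide scanner and no trained detector.  A synthetic slide is a
tile grid whose foreground is a union of elliptical blobs (an irregular
tissue section), with per-tile, per-type expected cell counts drawn from a
log-Gaussian random field:

    log lambda_j(t) = log m_j + delta_j - (sig_sp^2 + sig_sl^2)/2
                      + sig_sp * G_j(t) + sig_sl * v_j

where ``m_j`` is the cohort mean density of cell type ``j`` (cells per
100-µm square), ``delta_j`` an optional clinical log-shift, ``G_j`` a unit-
variance Gaussian field smoothed over ``correlation_length`` tiles, and
``v`` a slide-level random effect.  Both ``G`` and ``v`` carry a target
cross-type correlation matrix, so fibroblast-rich regions are epithelium-
poor and so on.  The −σ²/2 terms make ``E[lambda_j] = m_j exp(delta_j)``
exact.  Tile counts are Poisson given ``lambda`` times the tile area, and
nucleus coordinates are uniform within the tile.

Spatial correlation is the point: neighboring tiles have similar expected
counts, which is precisely the structure that makes systematic random
sampling outperform simple random sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import TileGrid
from .profiling import (
    CELL_TYPES,
    DEFAULT_MICRONS_PER_PX,
    DEFAULT_PATCH_SIZE_PX,
    N_TYPES,
    CellMap,
    SlideProfile,
    tile_area_factor,
)

logger = logging.getLogger(__name__)

#: Cohort mean cell densities (cells per 100-µm square) by type.
DEFAULT_MEAN_DENSITY: dict[str, float] = {
    "epithelial": 21.3,
    "inflammatory": 5.52,
    "fibroblast": 5.64,
    "other": 2.43,
}

#: Default cross-type correlation target for the latent fields (signed,
#: symmetric, unit diagonal): epithelial crowds out fibroblasts and "other"
#: cells, fibroblasts and "other" co-occur.
DEFAULT_CROSS_TYPE_CORRELATION = np.array(
    [
        [1.00, 0.20, -0.59, -0.63],
        [0.20, 1.00, -0.34, -0.13],
        [-0.59, -0.34, 1.00, 0.56],
        [-0.63, -0.13, 0.56, 1.00],
    ]
)


@dataclass(frozen=True)
class ClinicalEffect:
    """A binary clinical variable and (optionally) its effect on densities.

    ``group_fraction`` of slides get the second level.  ``group_means`` maps
    a cell-type name to its (level0, level1) target mean densities; types not
    listed are unshifted, and ``group_means=None`` yields a pure label (a
    null variable).
    """

    name: str
    group_fraction: float
    levels: tuple[str, str] = ("0", "1")
    group_means: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.group_fraction < 1.0:
            raise ValueError("group_fraction must be in (0, 1)")
        if self.group_means is not None:
            for t, (m0, m1) in self.group_means.items():
                if t not in CELL_TYPES:
                    raise ValueError(f"unknown cell type {t!r}")
                if m0 <= 0 or m1 <= 0:
                    raise ValueError("group mean densities must be positive")


def metastasis_effect() -> ClinicalEffect:
    """Default worked effect: fibroblast density 5.3 vs 7.7 in 120/21 groups."""
    return ClinicalEffect(
        name="metastasis",
        group_fraction=21 / 141,
        levels=("M0", "M1"),
        group_means={"fibroblast": (5.3, 7.7)},
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the source cohort: 142 slides of ~900 foreground tiles,
    four cell types at the observed global mean densities, positive spatial
    autocorrelation over a few tiles, and the observed cross-type correlation
    signs.  ``artifact_fraction`` is 1−γ, the chance that a foreground tile
    is a gray artifact.
    """

    n_slides: int = 142
    grid_shape: tuple[int, int] = (36, 36)
    target_foreground_tiles: int = 900
    artifact_fraction: float = 0.0
    mean_density: Mapping[str, float] | Sequence[float] | None = None
    correlation_length: float = 3.0
    cross_type_correlation: np.ndarray | None = None
    spatial_log_sd: float = 0.5
    slide_log_sd: float = 0.35
    clinical_effects: tuple[ClinicalEffect, ...] = ()
    patch_size_px: int = DEFAULT_PATCH_SIZE_PX
    microns_per_px: float = DEFAULT_MICRONS_PER_PX

    def __post_init__(self) -> None:
        md = self.mean_density
        if md is None:
            md = DEFAULT_MEAN_DENSITY
        if isinstance(md, Mapping):
            vec = np.array([float(md[t]) for t in CELL_TYPES])
        else:
            vec = np.asarray(md, dtype=float)
        if vec.shape != (N_TYPES,):
            raise ValueError(f"mean_density must give {N_TYPES} values")
        if np.any(vec < 0):
            raise ValueError("mean densities must be >= 0")
        object.__setattr__(self, "mean_density", vec)

        corr = self.cross_type_correlation
        corr = DEFAULT_CROSS_TYPE_CORRELATION if corr is None else np.asarray(corr, float)
        if corr.shape != (N_TYPES, N_TYPES):
            raise ValueError("cross_type_correlation must be 4x4")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError("cross_type_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError("cross_type_correlation must have unit diagonal")
        object.__setattr__(self, "cross_type_correlation", corr)

        if self.n_slides < 1:
            raise ValueError("n_slides must be >= 1")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must be in [0, 1]")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        nr, nc = self.grid_shape
        if nr < 1 or nc < 1:
            raise ValueError("grid_shape must be positive")
        if self.target_foreground_tiles > nr * nc:
            raise ValueError(
                f"target_foreground_tiles ({self.target_foreground_tiles}) exceeds "
                f"grid capacity ({nr * nc})"
            )
        if self.spatial_log_sd < 0 or self.slide_log_sd < 0:
            raise ValueError("log-scale standard deviations must be >= 0")

    @property
    def gamma(self) -> float:
        """Expected non-artifact fraction of foreground tiles."""
        return 1.0 - self.artifact_fraction


# ---------------------------------------------------------------------------
# Latent field machinery
# ---------------------------------------------------------------------------


def nearest_correlation_psd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to the nearest unit-diagonal PSD correlation.

    Eigenvalues are clipped at ``eps`` and the result rescaled to a unit
    diagonal.  Raises if the repair flips the sign of any off-diagonal entry
    larger than ``eps`` in magnitude — a sign-respecting repair is required
    because the signs are the modeled quantity.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh(corr)
    if w.min() >= eps:
        return corr
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    off = ~np.eye(corr.shape[0], dtype=bool)
    flipped = off & (np.abs(corr) > eps) & (np.sign(fixed) != np.sign(corr))
    if np.any(flipped):
        raise ValueError(
            "correlation target is not positive semidefinite and the nearest-PSD "
            "repair cannot preserve its sign pattern"
        )
    return fixed


def _smoothing_norm(shape: tuple[int, int], sigma: float) -> float:
    """L2 norm of the periodic Gaussian smoothing kernel on this grid."""
    impulse = np.zeros(shape)
    impulse[shape[0] // 2, shape[1] // 2] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma, mode="wrap")
    return float(np.sqrt((k**2).sum()))


def _correlated_unit_fields(
    grid_shape: tuple[int, int],
    correlation_length: float,
    corr_chol: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(4, nr, nc) Gaussian fields: unit variance, cross-correlated, smoothed.

    White noise is mixed across types by the Cholesky factor of the target
    correlation, then each type's plane is smoothed with a periodic Gaussian
    kernel of scale ``correlation_length`` tiles and renormalized to unit
    marginal variance.  Smoothing is applied identically per type, so the
    pointwise cross-type correlation is unchanged by it.
    """
    white = rng.standard_normal((N_TYPES,) + tuple(grid_shape))
    mixed = np.einsum("jk,k...->j...", corr_chol, white)
    if correlation_length <= 0:
        return mixed
    norm = _smoothing_norm(tuple(grid_shape), correlation_length)
    smooth = np.empty_like(mixed)
    for j in range(N_TYPES):
        smooth[j] = ndimage.gaussian_filter(mixed[j], correlation_length, mode="wrap")
    return smooth / norm


def generate_intensity_field(
    grid_shape: tuple[int, int],
    correlation_length: float,
    mean_density: Sequence[float] | Mapping[str, float] | None = None,
    cross_type_correlation: np.ndarray | None = None,
    seed: int | Sequence[int] = 0,
    spatial_log_sd: float = 0.5,
    log_shift: Sequence[float] | None = None,
    slide_effect: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-tile, per-type expected cell densities for one slide.

    Returns a ``(4, n_rows, n_cols)`` nonnegative field in cells per 100-µm
    square whose per-type expectation equals ``mean_density`` (times
    ``exp(log_shift)`` where given).  ``correlation_length = 0`` yields
    spatially independent tiles; larger values give smoother fields with
    higher neighboring-tile correlation.  ``slide_effect`` is an optional
    additive 4-vector on the log scale (a slide-level random effect supplied
    by the cohort generator).
    """
    nr, nc = grid_shape
    if nr < 1 or nc < 1:
        raise ValueError("grid_shape must be positive")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    if spatial_log_sd < 0:
        raise ValueError("spatial_log_sd must be >= 0")
    if mean_density is None:
        mean_density = DEFAULT_MEAN_DENSITY
    if isinstance(mean_density, Mapping):
        m = np.array([float(mean_density[t]) for t in CELL_TYPES])
    else:
        m = np.asarray(mean_density, dtype=float)
    if m.shape != (N_TYPES,) or np.any(m < 0):
        raise ValueError(f"mean_density must be {N_TYPES} nonnegative values")
    corr = (
        DEFAULT_CROSS_TYPE_CORRELATION
        if cross_type_correlation is None
        else np.asarray(cross_type_correlation, float)
    )
    corr = nearest_correlation_psd(corr)
    # tiny jitter keeps Cholesky defined at eigenvalue ~eps
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(N_TYPES))

    rng = np.random.default_rng(seed)
    G = _correlated_unit_fields((nr, nc), correlation_length, chol, rng)

    shift = np.zeros(N_TYPES) if log_shift is None else np.asarray(log_shift, float)
    sl = np.zeros(N_TYPES) if slide_effect is None else np.asarray(slide_effect, float)
    log_field = (
        shift[:, None, None]
        - 0.5 * spatial_log_sd**2
        + spatial_log_sd * G
        + sl[:, None, None]
    )
    field = m[:, None, None] * np.exp(log_field)
    field[m == 0] = 0.0
    return field


def lag1_autocorrelation(plane: np.ndarray) -> float:
    """Empirical lag-1 spatial correlation of a 2-D field (both axes pooled)."""
    plane = np.asarray(plane, dtype=float)
    pairs_a = np.column_stack([plane[:-1, :].ravel(), plane[1:, :].ravel()])
    pairs_b = np.column_stack([plane[:, :-1].ravel(), plane[:, 1:].ravel()])
    pairs = np.vstack([pairs_a, pairs_b])
    return float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])


# ---------------------------------------------------------------------------
# Foreground geometry
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def _neighbor_counts(mask: np.ndarray) -> np.ndarray:
    return ndimage.convolve(mask.astype(int), _NEIGHBOR_KERNEL, mode="constant")


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    theta: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def elliptical_foreground(
    grid_shape: tuple[int, int],
    target_tiles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blobby tissue-like foreground with exactly ``target_tiles`` tiles.

    A union of random ellipses is grown until it covers at least the target,
    then adjusted tile-by-tile — peeling the most exposed boundary tiles or
    dilating into the best-connected background tiles — until the count is
    exact.  The result is one or a few connected blobs with irregular edges,
    mimicking a tissue section.
    """
    nr, nc = grid_shape
    capacity = nr * nc
    if target_tiles > capacity:
        raise ValueError(f"target_tiles ({target_tiles}) exceeds grid capacity ({capacity})")
    mask = np.zeros(grid_shape, dtype=bool)
    if target_tiles == 0:
        return mask

    # primary blob ~80% of target, then smaller overlapping blobs
    blob_areas = [0.8 * target_tiles]
    while True:
        if mask.sum() >= target_tiles:
            break
        area = blob_areas.pop(0) if blob_areas else 0.2 * target_tiles
        base = math.sqrt(area / math.pi)
        ecc = rng.uniform(0.6, 1.6)
        axes = (max(base * ecc, 0.6), max(base / ecc, 0.6))
        if mask.any():
            fg = np.argwhere(mask)
            center = tuple(fg[rng.integers(len(fg))] + rng.normal(0, base, 2))
        else:
            center = (rng.uniform(0.35, 0.65) * nr, rng.uniform(0.35, 0.65) * nc)
        mask |= _ellipse_mask(grid_shape, center, axes, rng.uniform(0, math.pi))

    # exact adjustment: peel most-exposed tiles / fill best-connected gaps
    while mask.sum() > target_tiles:
        nb = _neighbor_counts(mask)
        cand = np.argwhere(mask & (nb == nb[mask].min()))
        r, c = cand[rng.integers(len(cand))]
        mask[r, c] = False
    while mask.sum() < target_tiles:
        nb = _neighbor_counts(mask)
        frontier = ~mask & (nb > 0)
        if not frontier.any():  # mask vanished entirely: reseed one tile
            mask[nr // 2, nc // 2] = True
            continue
        cand = np.argwhere(frontier & (nb == nb[frontier].max()))
        r, c = cand[rng.integers(len(cand))]
        mask[r, c] = True
    return mask


# ---------------------------------------------------------------------------
# Slides and cohorts
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSlide:
    """One simulated slide: tile grid, per-tile truth counts, clinical record.

    Ground-truth cell maps are materialized on demand from the stored per-tile
    counts and a per-tile random stream, so a cohort of 142 slides holds count
    arrays, not millions of coordinates; :meth:`cell_map` is deterministic and
    independent of the order in which tiles are requested.
    """

    slide_id: str
    tile_grid: TileGrid
    counts: np.ndarray  # (n_rows, n_cols, 4) int, zero off the usable tiles
    intensity: np.ndarray  # (4, n_rows, n_cols) expected densities
    clinical_record: dict[str, object] = field(default_factory=dict)
    cell_seed: tuple[int, ...] = (0,)

    def cell_map(self, row: int, col: int) -> CellMap:
        """Ground-truth cell map of one usable foreground tile."""
        if not self.tile_grid.tissue[row, col]:
            raise ValueError(f"tile ({row}, {col}) is background: no cell map")
        if self.tile_grid.artifact[row, col]:
            raise ValueError(f"tile ({row}, {col}) is an artifact: no cell map")
        counts = self.counts[row, col]
        n = int(counts.sum())
        rng = np.random.default_rng([*self.cell_seed, int(row), int(col)])
        P = self.tile_grid.patch_size_px
        x = rng.uniform(0, P, size=n)
        y = rng.uniform(0, P, size=n)
        labels = np.repeat(np.arange(N_TYPES), counts)
        return CellMap(x, y, labels)

    def true_profile(self) -> SlideProfile:
        """Exhaustive ground-truth slide profile (all usable tiles, no noise).

        Equals running the pipeline with an exhaustive plan and a perfect
        identifier, computed directly from the stored counts.
        """
        usable = self.tile_grid.usable
        n_T = int(usable.sum())
        if n_T == 0:
            raise ValueError(f"slide {self.slide_id} has no usable tiles")
        area = tile_area_factor(self.tile_grid.patch_size_px, self.tile_grid.microns_per_px)
        mean_counts = self.counts[usable].mean(axis=0)
        return SlideProfile(mean_counts / area, n_T=n_T, slide_id=self.slide_id)


def _clinical_log_shift(config: CohortConfig, record: dict[str, object]) -> np.ndarray:
    """Per-type log-density shift implied by a slide's group memberships."""
    shift = np.zeros(N_TYPES)
    for eff in config.clinical_effects:
        if eff.group_means is None or eff.name not in record:
            continue
        level = 0 if record[eff.name] == eff.levels[0] else 1
        for t, means in eff.group_means.items():
            j = CELL_TYPES.index(t)
            base = config.mean_density[j]
            if base <= 0:
                raise ValueError(f"cannot shift type {t!r} with zero base density")
            shift[j] += math.log(means[level] / base)
    return shift


def generate_slide(
    config: CohortConfig,
    slide_index: int,
    seed: int,
    clinical_record: dict[str, object] | None = None,
) -> SyntheticSlide:
    """Generate one synthetic slide, deterministically from (config, seed, index)."""
    record = dict(clinical_record or {})
    nr, nc = config.grid_shape

    mask_rng = np.random.default_rng([seed, slide_index, 1])
    tissue = elliptical_foreground((nr, nc), config.target_foreground_tiles, mask_rng)

    art_rng = np.random.default_rng([seed, slide_index, 2])
    artifact = tissue & (art_rng.random((nr, nc)) < config.artifact_fraction)

    # slide-level random effect, cross-correlated like the spatial field
    eff_rng = np.random.default_rng([seed, slide_index, 3])
    corr = nearest_correlation_psd(config.cross_type_correlation)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(N_TYPES))
    v = config.slide_log_sd * (chol @ eff_rng.standard_normal(N_TYPES))
    v -= 0.5 * config.slide_log_sd**2  # keep E[exp(effect)] = 1

    field = generate_intensity_field(
        (nr, nc),
        config.correlation_length,
        config.mean_density,
        config.cross_type_correlation,
        seed=[seed, slide_index, 4],
        spatial_log_sd=config.spatial_log_sd,
        log_shift=_clinical_log_shift(config, record),
        slide_effect=v,
    )

    area = tile_area_factor(config.patch_size_px, config.microns_per_px)
    count_rng = np.random.default_rng([seed, slide_index, 5])
    usable = tissue & ~artifact
    counts = np.zeros((nr, nc, N_TYPES), dtype=np.int64)
    lam = np.moveaxis(field, 0, -1) * area  # (nr, nc, 4) expected counts/tile
    counts[usable] = count_rng.poisson(lam[usable])

    grid = TileGrid(
        tissue,
        artifact,
        patch_size_px=config.patch_size_px,
        microns_per_px=config.microns_per_px,
    )
    return SyntheticSlide(
        slide_id=f"S{slide_index:04d}",
        tile_grid=grid,
        counts=counts,
        intensity=field,
        clinical_record=record,
        cell_seed=(seed, slide_index, 6),
    )


def generate_clinical_cohort(
    config: CohortConfig, seed: int
) -> tuple[list[SyntheticSlide], pd.DataFrame]:
    """Generate a cohort of slides with matched clinical labels.

    Group labels are assigned by exact allocation: ``round(n * fraction)``
    slides drawn at random get the second level of each variable, so the
    design group sizes are met exactly.  Where a variable carries target
    group means, each member slide's log-densities are shifted so the
    realized group means match those targets in expectation.  With an empty
    effect list this is a valid null cohort (labels, no shifts).
    """
    label_rng = np.random.default_rng([seed, 10_000_019])
    n = config.n_slides
    records: list[dict[str, object]] = [{} for _ in range(n)]
    for eff in config.clinical_effects:
        n1 = int(round(n * eff.group_fraction))
        n1 = min(max(n1, 1), n - 1)  # both groups non-empty
        members = set(label_rng.permutation(n)[:n1].tolist())
        for i in range(n):
            records[i][eff.name] = eff.levels[1] if i in members else eff.levels[0]

    slides = [generate_slide(config, i, seed, clinical_record=records[i]) for i in range(n)]
    clinical = pd.DataFrame(records, index=[s.slide_id for s in slides])
    clinical.index.name = "slide_id"
    return slides, clinical


def cohort_profiles(slides: Sequence[SyntheticSlide]) -> pd.DataFrame:
    """Ground-truth exhaustive profiles of a cohort as a slide x type table."""
    rows = {s.slide_id: s.true_profile().values for s in slides}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CELL_TYPES)).rename_axis(
        "slide_id"
    )
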