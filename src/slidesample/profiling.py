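"""Cell maps and cellularity profiles.

A *cell map* is the output of a cell-identification step on one tile: a set
of nucleus locations, each labeled with one of four cell types (epithelial,
inflammatory, fibroblast, "other").  A *tile profile* counts the cells of
each type in a tile and normalises by tile area, giving densities in cells
per 100-µm square.  A *slide profile* is the component-wise mean of the tile
profiles over the sampled tiles — the slide's morphological profile.

The identification step itself is behind the :class:`CellIdentifier`
contract: any callable ``(cell_map, row, col) -> CellMap`` can be plugged in.
Two implementations ship here — :class:`PerfectIdentifier`, which returns the
ground truth unchanged, and :class:`OracleIdentifier`, a stochastic stand-in
for a trained detector/classifier pair with a configurable miss rate and
label-confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Protocol, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .sampling import SamplingPlan, SampleSet

logger = logging.getLogger(__name__)

#: Canonical cell-type order used everywhere in the package.
CELL_TYPES: tuple[str, ...] = ("epithelial", "inflammatory", "fibroblast", "other")

N_TYPES = len(CELL_TYPES)

#: Default tile geometry: 500 px at 20X (~0.5 µm/px), i.e. a 250-µm square.
DEFAULT_PATCH_SIZE_PX = 500
DEFAULT_MICRONS_PER_PX = 0.5

#: Default stand-in identifier calibration: 0.65 mean detection accuracy
#: (miss rate 0.35) and 0.76 mean classification accuracy.
DEFAULT_MISS_RATE = 0.35
DEFAULT_CLASSIFICATION_ACCURACY = 0.76


class EmptySampleError(ValueError):
    """Raised when a slide profile is requested for an empty tile sample."""


def default_confusion_matrix(accuracy: float = DEFAULT_CLASSIFICATION_ACCURACY) -> np.ndarray:
    """Symmetric confusion matrix with ``accuracy`` on the diagonal.

    Off-diagonal mass is spread evenly over the other three types.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {accuracy}")
    off = (1.0 - accuracy) / (N_TYPES - 1)
    mat = np.full((N_TYPES, N_TYPES), off)
    np.fill_diagonal(mat, accuracy)
    return mat


@dataclass(frozen=True)
class CellMap:
    """Located, typed cell nuclei for one tile.

    Parameters
    ----------
    x, y : ndarray of float
        Tile-local nucleus coordinates in pixels, ``0 <= x, y < patch_size_px``.
    labels : ndarray of int
        Cell-type codes indexing into :data:`CELL_TYPES`.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        labels = np.asarray(self.labels, dtype=np.int64)
        if not (x.shape == y.shape == labels.shape) or x.ndim != 1:
            raise ValueError("x, y and labels must be 1-D arrays of equal length")
        if labels.size and (labels.min() < 0 or labels.max() >= N_TYPES):
            raise ValueError(f"labels must be in [0, {N_TYPES})")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "labels", labels)

    @property
    def n_M(self) -> int:
        """Number of cells in the map."""
        return int(self.labels.size)

    def type_counts(self) -> np.ndarray:
        """Per-type cell counts, ordered as :data:`CELL_TYPES`."""
        return np.bincount(self.labels, minlength=N_TYPES)

    def coordinates(self) -> np.ndarray:
        """``(n_M, 2)`` array of ``(x, y)`` coordinates."""
        return np.column_stack([self.x, self.y])

    @classmethod
    def empty(cls) -> "CellMap":
        return cls(np.empty(0), np.empty(0), np.empty(0, dtype=np.int64))

    @classmethod
    def from_cells(cls, cells: Sequence[tuple[float, float, str]]) -> "CellMap":
        """Build a map from ``(x, y, type_name)`` triples."""
        if not cells:
            return cls.empty()
        xs, ys, names = zip(*cells)
        labels = np.array([CELL_TYPES.index(n) for n in names], dtype=np.int64)
        return cls(np.asarray(xs, float), np.asarray(ys, float), labels)


def tile_area_factor(
    patch_size_px: int = DEFAULT_PATCH_SIZE_PX,
    microns_per_px: float = DEFAULT_MICRONS_PER_PX,
) -> float:
    """Tile area in 100-µm squares (6.25 for the default 500 px @ 0.5 µm/px)."""
    if patch_size_px <= 0:
        raise ValueError(f"patch_size_px must be positive, got {patch_size_px}")
    if microns_per_px <= 0:
        raise ValueError(f"microns_per_px must be positive, got {microns_per_px}")
    side_100um = patch_size_px * microns_per_px / 100.0
    return side_100um**2


def tile_profile(
    cell_map: CellMap,
    patch_size_px: int = DEFAULT_PATCH_SIZE_PX,
    microns_per_px: float = DEFAULT_MICRONS_PER_PX,
) -> np.ndarray:
    """Per-type cell densities of one tile, in cells per 100-µm square.

    The density of type ``j`` is the count of type-``j`` cells divided by the
    tile area expressed in 100-µm squares; for the default 250-µm tile the
    divisor is 6.25, so 10 cells correspond to a density of 1.6.
    """
    area = tile_area_factor(patch_size_px, microns_per_px)
    return cell_map.type_counts() / area


@dataclass(frozen=True)
class SlideProfile:
    """Morphological profile of one slide: mean tile densities by cell type.

    ``values`` is a 4-vector in cells per 100-µm square, ordered as
    :data:`CELL_TYPES`; ``n_T`` is the number of tiles averaged.
    """

    values: np.ndarray
    n_T: int
    slide_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_TYPES,):
            raise ValueError(f"profile must have {N_TYPES} entries")
        if np.any(v < 0):
            raise ValueError("profile densities must be nonnegative")
        if self.n_T < 1:
            raise EmptySampleError("a slide profile requires at least one tile")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CELL_TYPES, self.values.tolist()))


def slide_profile(
    tile_profiles: np.ndarray | Sequence[np.ndarray],
    slide_id: str | None = None,
) -> SlideProfile:
    """Average tile profiles into a slide profile (undefined for no tiles)."""
    arr = np.atleast_2d(np.asarray(tile_profiles, dtype=float))
    if arr.size == 0 or arr.shape[0] == 0:
        raise EmptySampleError("cannot average an empty set of tile profiles")
    if arr.shape[1] != N_TYPES:
        raise ValueError(f"tile profiles must have {N_TYPES} columns")
    return SlideProfile(arr.mean(axis=0), n_T=arr.shape[0], slide_id=slide_id)


# ---------------------------------------------------------------------------
# Cell identification contract
# ---------------------------------------------------------------------------


def _validate_confusion(confusion_matrix: np.ndarray) -> np.ndarray:
    mat = np.asarray(confusion_matrix, dtype=float)
    if mat.shape != (N_TYPES, N_TYPES):
        raise ValueError(f"confusion matrix must be {N_TYPES}x{N_TYPES}")
    if np.any(mat < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("confusion matrix rows must sum to 1")
    return mat


def oracle_identifier(
    ground_truth_map: CellMap,
    miss_rate: float = DEFAULT_MISS_RATE,
    confusion_matrix: np.ndarray | None = None,
    seed: int | Sequence[int] = 0,
) -> CellMap:
    """Perturb a ground-truth cell map to emulate an imperfect identifier.

    Each truth cell is dropped independently with probability ``miss_rate``
    (detection misses); every surviving cell is relabeled by one draw from its
    true type's row of ``confusion_matrix`` (classification errors).  With the
    defaults the retained fraction is 0.65 and the per-cell probability of a
    correct label is 0.76, the calibration of the identifier this stands in
    for.
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError(f"miss_rate must be in [0, 1], got {miss_rate}")
    if confusion_matrix is None:
        confusion_matrix = default_confusion_matrix()
    mat = _validate_confusion(confusion_matrix)
    rng = np.random.default_rng(seed)

    keep = rng.random(ground_truth_map.n_M) >= miss_rate
    x = ground_truth_map.x[keep]
    y = ground_truth_map.y[keep]
    true_labels = ground_truth_map.labels[keep]
    if true_labels.size == 0:
        return CellMap.empty()
    # inverse-CDF draw from each cell's confusion row
    cum = np.cumsum(mat, axis=1)
    u = rng.random(true_labels.size)
    new_labels = (u[:, None] > cum[true_labels]).sum(axis=1)
    return CellMap(x, y, new_labels.astype(np.int64))


class CellIdentifier(Protocol):
    """Anything mapping ``(ground_truth, row, col) -> CellMap``.

    Implementations must be deterministic given their own seed: calling twice
    with the same tile yields the identical cell map, regardless of the order
    or subset of tiles processed.
    """

    def __call__(self, cell_map: CellMap, row: int, col: int) -> CellMap: ...


class PerfectIdentifier:
    """Identity identifier: returns the ground-truth cell map unchanged."""

    def __call__(self, cell_map: CellMap, row: int, col: int) -> CellMap:
        return cell_map


class OracleIdentifier:
    """Deterministic per-tile wrapper around :func:`oracle_identifier`.

    The per-tile random stream is derived from ``(seed, row, col)``, so the
    same tile always yields the same output — mirroring a trained network,
    which is deterministic on a given patch — while different tiles get
    independent noise.
    """

    def __init__(
        self,
        miss_rate: float = DEFAULT_MISS_RATE,
        confusion_matrix: np.ndarray | None = None,
        seed: int = 0,
    ) -> None:
        self.miss_rate = float(miss_rate)
        self.confusion_matrix = _validate_confusion(
            default_confusion_matrix() if confusion_matrix is None else confusion_matrix
        )
        self.seed = int(seed)

    def __call__(self, cell_map: CellMap, row: int, col: int) -> CellMap:
        return oracle_identifier(
            cell_map,
            miss_rate=self.miss_rate,
            confusion_matrix=self.confusion_matrix,
            seed=[self.seed, int(row), int(col)],
        )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class SlideLike(Protocol):
    """Minimal slide interface: a tile grid plus per-tile ground truth."""

    @property
    def tile_grid(self): ...  # -> TileGrid

    def cell_map(self, row: int, col: int) -> CellMap: ...


@dataclass
class PipelineResult:
    """Audit record of one slide's pass through the sampling pipeline."""

    profile: SlideProfile
    sample: "SampleSet"
    tile_profiles: np.ndarray = field(repr=False)


def run_pipeline(
    slide: SlideLike,
    identifier: CellIdentifier,
    plan: "SamplingPlan",
) -> PipelineResult:
    """Sample tiles, identify cells, and average into a slide profile.

    Composes the four stages — tile selection according to ``plan``, cell
    identification on each sampled tile, per-tile density profiles, and the
    slide-level mean — and records the sample set and tile profiles for audit.

    Raises
    ------
    EmptySampleError
        If the plan selects no tiles (the slide is then excluded from batch
        statistics by the caller, never zero-filled).
    """
    from .sampling import draw_sample  # local import to avoid a cycle

    grid = slide.tile_grid
    sample = draw_sample(grid, plan)
    if sample.n_T == 0:
        raise EmptySampleError(
            f"sampling plan {plan.policy!r} selected no tiles on slide "
            f"{getattr(slide, 'slide_id', '?')}"
        )
    profiles = np.empty((sample.n_T, N_TYPES), dtype=float)
    for i, (r, c) in enumerate(sample.tiles):
        identified = identifier(slide.cell_map(r, c), r, c)
        profiles[i] = tile_profile(identified, grid.patch_size_px, grid.microns_per_px)
    prof = slide_profile(profiles, slide_id=getattr(slide, "slide_id", None))
    return PipelineResult(profile=prof, sample=sample, tile_profiles=profiles)
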