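"""Plain-text interchange formats for cohorts, profiles and cell maps.

A cohort directory holds, per slide, a tile-resolution foreground mask
(PNG, 0 = background, 255 = foreground), a cell-map CSV
(``tile_row, tile_col, x_px, y_px, cell_type``) and, cohort-wide, a clinical
TSV (``slide_id`` + one column per variable) and a JSON manifest recording
the grid geometry and artifact tiles.  The CSV format is also the plug-in
point for real data: any external detector that writes cell maps in this
shape can drive the profiling pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .cohort import SyntheticSlide
from .grid import TileGrid
from .profiling import CELL_TYPES, CellMap


def write_mask_png(grid: TileGrid, path: str | Path) -> None:
    """Write a tile-resolution foreground mask (255 = foreground)."""
    img = (grid.tissue.astype(np.uint8)) * 255
    Image.fromarray(img, mode="L").save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    """Load a mask PNG as a boolean raster."""
    return np.asarray(Image.open(path).convert("L")) > 127


def write_cell_maps_csv(slide: SyntheticSlide, path: str | Path) -> None:
    """Write all usable tiles' ground-truth cell maps for one slide."""
    rows = []
    for r, c in slide.tile_grid.usable_tiles():
        cm = slide.cell_map(r, c)
        for x, y, lab in zip(cm.x, cm.y, cm.labels):
            rows.append((r, c, x, y, CELL_TYPES[lab]))
    frame = pd.DataFrame(
        rows, columns=["tile_row", "tile_col", "x_px", "y_px", "cell_type"]
    )
    frame.to_csv(path, index=False)


def load_cell_maps_csv(path: str | Path) -> dict[tuple[int, int], CellMap]:
    """Load per-tile cell maps from the interchange CSV."""
    frame = pd.read_csv(path)
    maps: dict[tuple[int, int], CellMap] = {}
    for (r, c), part in frame.groupby(["tile_row", "tile_col"]):
        labels = np.array([CELL_TYPES.index(t) for t in part["cell_type"]])
        maps[(int(r), int(c))] = CellMap(
            part["x_px"].to_numpy(float), part["y_px"].to_numpy(float), labels
        )
    return maps


@dataclass
class SlideData:
    """A slide assembled from loaded files, pipeline-compatible."""

    slide_id: str
    tile_grid: TileGrid
    cell_maps: Mapping[tuple[int, int], CellMap]

    def cell_map(self, row: int, col: int) -> CellMap:
        try:
            return self.cell_maps[(row, col)]
        except KeyError:
            return CellMap.empty()


def write_clinical_tsv(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t")


def load_clinical_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="slide_id")


def write_profiles_csv(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.rename_axis("slide_id").to_csv(path)


def load_profiles_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="slide_id")


def write_cohort(
    slides: Sequence[SyntheticSlide],
    clinical: pd.DataFrame,
    out_dir: str | Path,
    seed: int | None = None,
) -> None:
    """Write a full synthetic cohort: masks, cell maps, clinical table, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"seed": seed, "slides": []}
    for slide in slides:
        grid = slide.tile_grid
        write_mask_png(grid, out / f"{slide.slide_id}_mask.png")
        write_cell_maps_csv(slide, out / f"{slide.slide_id}_cells.csv")
        manifest["slides"].append(
            {
                "slide_id": slide.slide_id,
                "n_rows": grid.n_rows,
                "n_cols": grid.n_cols,
                "patch_size_px": grid.patch_size_px,
                "microns_per_px": grid.microns_per_px,
                "n_F": grid.n_F,
                "artifact_tiles": [list(t) for t in grid.tiles_where(grid.artifact)],
            }
        )
    write_clinical_tsv(clinical, out / "clinical.tsv")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
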