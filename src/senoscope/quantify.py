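"""Area-normalised per-cell fluorescence readouts.

Raw fluorescence is divided by the 2-D projected area of each cell
(mask pixel count x squared pixel size, µm²) so that changes in organelle
content are decoupled from cell spreading.  Two normalisations coexist:

* per-pixel intensity *densities* (a.u./µm², one value per in-mask pixel) —
  the distributional readout used by the lysosomal arm;
* the per-cell *mean density* (integrated in-mask intensity / area) — the
  single-scalar readout used by the mitochondrial membrane-potential arm.

The nuclear/cytoplasmic enrichment ratio (mean nuclear intensity divided by
mean cytoplasmic intensity) quantifies p16^INK4a partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyMaskError,
    MaskOverlapError,
    ShapeMismatchError,
    UndefinedRatioError,
)
from .image_io import CellImage, CellMask, load_image, load_mask, resolve_pixel_size

__all__ = [
    "CellRecord",
    "EnrichmentRecord",
    "projected_area",
    "pixel_densities",
    "mean_density",
    "nc_enrichment",
    "quantify_cell",
    "quantify_manifest",
]


@dataclass
class CellRecord:
    """Per-cell area-normalised readouts for one (donor, inducer) condition."""

    cell_id: str
    donor: str
    inducer: str
    area_um2: float
    density_values: np.ndarray  # a.u./µm², one per in-mask pixel
    mean_density: float  # a.u./µm²
    n_pixels: int = 0

    def __post_init__(self) -> None:
        if not self.area_um2 > 0:
            raise ValueError("area_um2 must be positive")
        self.density_values = np.asarray(self.density_values, dtype=float)
        if np.any(self.density_values < 0):
            raise ValueError("density values must be non-negative")


@dataclass(frozen=True)
class EnrichmentRecord:
    """Nuclear/cytoplasmic enrichment for one cell (dimensionless)."""

    cell_id: str
    nc_ratio: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.nc_ratio) or self.nc_ratio < 0:
            raise ValueError(f"nc_ratio must be finite and >= 0, got {self.nc_ratio}")


def projected_area(mask: CellMask, pixel_size: float) -> float:
    """Projected 2-D cell area in µm²: true-pixel count x pixel_size²."""
    if not pixel_size > 0:
        raise ValueError(f"pixel_size must be positive, got {pixel_size}")
    n = mask.n_pixels
    if n == 0:  # unreachable through CellMask, kept for raw callers
        raise EmptyMaskError("cannot compute area of an empty mask")
    return n * pixel_size ** 2


def _check_shapes(image: CellImage, mask: CellMask) -> None:
    if image.shape != mask.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} != mask shape {mask.shape}")


def pixel_densities(image: CellImage, mask: CellMask, area: float) -> np.ndarray:
    """Per-pixel intensity densities: each in-mask raw value / area (a.u./µm²)."""
    _check_shapes(image, mask)
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    return image.plane[mask.region].astype(float) / area


def mean_density(image: CellImage, mask: CellMask, area: float) -> float:
    """Integrated in-mask fluorescence divided by cell area (a.u./µm²)."""
    _check_shapes(image, mask)
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    return float(image.plane[mask.region].sum()) / area


def nc_enrichment(image: CellImage, nuclear_mask: CellMask,
                  cytoplasm_mask: CellMask) -> float:
    """Mean nuclear intensity / mean cytoplasmic intensity."""
    _check_shapes(image, nuclear_mask)
    _check_shapes(image, cytoplasm_mask)
    if np.any(nuclear_mask.region & cytoplasm_mask.region):
        raise MaskOverlapError("nuclear and cytoplasmic masks overlap")
    nuc_mean = float(image.plane[nuclear_mask.region].mean())
    cyt_mean = float(image.plane[cytoplasm_mask.region].mean())
    if cyt_mean == 0:
        raise UndefinedRatioError("cytoplasmic mean intensity is zero")
    return nuc_mean / cyt_mean


def quantify_cell(image: CellImage, mask: CellMask, cell_id: str = "",
                  donor: str = "", inducer: str = "") -> CellRecord:
    """Full per-cell readout: area, per-pixel densities and mean density."""
    pixel_size = resolve_pixel_size(image.meta)
    area = projected_area(mask, pixel_size)
    densities = pixel_densities(image, mask, area)
    return CellRecord(
        cell_id=cell_id,
        donor=donor,
        inducer=inducer,
        area_um2=area,
        density_values=densities,
        mean_density=mean_density(image, mask, area),
        n_pixels=mask.n_pixels,
    )


def quantify_manifest(manifest: str | Path | pd.DataFrame,
                      root: str | Path | None = None) -> list[CellRecord]:
    """Quantify every cell listed in a manifest.

    The manifest (CSV path or DataFrame) carries one row per cell with columns
    ``image_path, mask_path, donor, inducer, cell_id``; condition labels come
    from the manifest, never from filename parsing.  Relative paths are
    resolved against ``root`` (default: the manifest's directory).
    """
    if isinstance(manifest, pd.DataFrame):
        table = manifest
        base = Path(root) if root is not None else Path.cwd()
    else:
        manifest = Path(manifest)
        table = pd.read_csv(manifest)
        base = Path(root) if root is not None else manifest.parent

    required = {"image_path", "mask_path", "donor", "inducer", "cell_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")

    records = []
    for row in table.itertuples(index=False):
        image = load_image(base / str(row.image_path))
        mask = load_mask(base / str(row.mask_path), target_shape=image.shape)
        records.append(quantify_cell(image, mask, cell_id=str(row.cell_id),
                                     donor=str(row.donor), inducer=str(row.inducer)))
    return records


def records_to_frame(records: list[CellRecord]) -> pd.DataFrame:
    """Summary table (one row per cell) for CSV export."""
    return pd.DataFrame({
        "cell_id": [r.cell_id for r in records],
        "donor": [r.donor for r in records],
        "inducer": [r.inducer for r in records],
        "area_um2": [r.area_um2 for r in records],
        "mean_density": [r.mean_density for r in records],
        "n_pixels": [r.n_pixels for r in records],
    })
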