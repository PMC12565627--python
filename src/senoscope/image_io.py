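"""Loading of fluorescence stacks and binary cell masks.

Confocal exports arrive either as Zeiss CZI containers (dimension order
interpreted as C, Z, Y, X) or as plain multi-page TIFF.  Whatever the
container, the pipeline consumes a single 2-D plane: for 4-D data the first
channel is summed over z (extended-depth-of-focus style projection), for 3-D
data the first channel is taken directly, and 2-D data passes through.

Physical pixel sizes (µm) come from the CZI metadata or from a sidecar JSON
(``<stem>.json`` with keys ``pixel_size_x_um`` / ``pixel_size_y_um``); when
both axes are present their arithmetic mean is used as the isotropic pixel
size.

Masks are single-channel PNG rasters drawn manually; white (maximum-value)
pixels mark the cell region.  A mask is resized to the fluorescence array by
nearest-neighbour interpolation and thresholded at 50% of its maximum so the
same file works for 8- and 16-bit exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

from .errors import (
    DimensionalityError,
    EmptyMaskError,
    ImageIOError,
    MetadataError,
)

__all__ = [
    "ImageMeta",
    "CellImage",
    "CellMask",
    "load_image",
    "image_from_array",
    "reduce_to_plane",
    "resolve_pixel_size",
    "load_mask",
    "mask_from_array",
]


@dataclass(frozen=True)
class ImageMeta:
    """Physical metadata attached to a fluorescence plane."""

    pixel_size_x: float | None = None  # µm per pixel
    pixel_size_y: float | None = None  # µm per pixel
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        for name, value in (("pixel_size_x", self.pixel_size_x),
                            ("pixel_size_y", self.pixel_size_y)):
            if value is not None and not value > 0:
                raise MetadataError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CellImage:
    """A 2-D non-negative intensity raster plus its physical metadata."""

    plane: np.ndarray
    meta: ImageMeta = field(default_factory=ImageMeta)

    def __post_init__(self) -> None:
        plane = np.asarray(self.plane)
        if plane.ndim != 2:
            raise DimensionalityError(
                f"CellImage plane must be 2-D, got shape {plane.shape}")
        if np.any(plane < 0):
            raise ValueError("intensity plane contains negative values")
        object.__setattr__(self, "plane", plane)

    @property
    def shape(self) -> tuple[int, int]:
        return self.plane.shape


@dataclass(frozen=True)
class CellMask:
    """Boolean raster; ``True`` marks pixels inside the cell region."""

    region: np.ndarray

    def __post_init__(self) -> None:
        region = np.asarray(self.region)
        if region.ndim != 2:
            raise DimensionalityError(
                f"CellMask must be 2-D, got shape {region.shape}")
        if region.dtype != bool:
            region = region.astype(bool)
        if not region.any():
            raise EmptyMaskError("mask contains no in-cell (True) pixels")
        object.__setattr__(self, "region", region)

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape

    @property
    def n_pixels(self) -> int:
        return int(self.region.sum())


def reduce_to_plane(array: np.ndarray) -> np.ndarray:
    """Reduce a 2-D/3-D/4-D stack to the single analysis plane.

    4-D ``(channel, z, y, x)`` input: first channel summed over z.
    3-D ``(channel, y, x)`` input: first channel.
    2-D input: unchanged.
    """
    array = np.asarray(array)
    if array.ndim == 2:
        return array
    if array.ndim == 3:
        return array[0]
    if array.ndim == 4:
        return array[0].sum(axis=0)
    raise DimensionalityError(
        f"expected a 2-D, 3-D or 4-D array, got shape {array.shape}")


def _sidecar_meta(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def _czi_pixel_sizes(czi) -> tuple[float | None, float | None]:
    # Best effort: Zeiss stores scaling in metres under Scaling/Items/Distance.
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(czi.metadata())
        sizes: dict[str, float] = {}
        for dist in root.iter("Distance"):
            axis = dist.get("Id")
            value = dist.findtext("Value")
            if axis in ("X", "Y") and value is not None:
                sizes[axis] = float(value) * 1e6  # m -> µm
        return sizes.get("X"), sizes.get("Y")
    except Exception:
        return None, None


def load_image(path: str | Path) -> CellImage:
    """Load a CZI or TIFF stack and reduce it to a :class:`CellImage`.

    Metadata resolution order: CZI embedded scaling, then sidecar JSON.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    px = py = None
    if suffix == ".czi":
        try:
            import czifile
        except ImportError as exc:  # pragma: no cover - optional reader
            raise ImageIOError(
                f"cannot read {path}: the 'czifile' reader is not installed; "
                "convert to TIFF with a sidecar JSON instead") from exc
        try:
            with czifile.CziFile(path) as czi:
                array = np.squeeze(czi.asarray())
                px, py = _czi_pixel_sizes(czi)
        except ImageIOError:
            raise
        except Exception as exc:
            raise ImageIOError(f"cannot read CZI file {path}: {exc}") from exc
    else:
        try:
            array = tifffile.imread(path)
        except Exception as exc:
            raise ImageIOError(f"cannot read image file {path}: {exc}") from exc

    sidecar = _sidecar_meta(path)
    px = sidecar.get("pixel_size_x_um", px)
    py = sidecar.get("pixel_size_y_um", py)
    meta = ImageMeta(pixel_size_x=px, pixel_size_y=py, source_path=str(path))
    return CellImage(plane=reduce_to_plane(array), meta=meta)


def image_from_array(array: np.ndarray,
                     pixel_size_x: float | None = None,
                     pixel_size_y: float | None = None,
                     source: str = "<memory>") -> CellImage:
    """Build a :class:`CellImage` from an in-memory stack (2-D to 4-D)."""
    meta = ImageMeta(pixel_size_x=pixel_size_x, pixel_size_y=pixel_size_y,
                     source_path=source)
    return CellImage(plane=reduce_to_plane(array), meta=meta)


def resolve_pixel_size(meta: ImageMeta) -> float:
    """Isotropic pixel size in µm: the mean of the two axes when both are
    known, otherwise whichever one is present."""
    x, y = meta.pixel_size_x, meta.pixel_size_y
    if x is None and y is None:
        raise MetadataError(
            f"no pixel-size metadata available for {meta.source_path}")
    if x is None:
        return float(y)
    if y is None:
        return float(x)
    return (float(x) + float(y)) / 2.0


def _nearest_resize(array: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    if array.shape == tuple(target_shape):
        return array
    rows, cols = target_shape
    img = Image.fromarray(array)
    return np.asarray(img.resize((cols, rows), resample=Image.NEAREST))


def mask_from_array(array: np.ndarray,
                    target_shape: tuple[int, int] | None = None,
                    fill_holes: bool = False) -> CellMask:
    """Threshold a raster to a boolean mask, optionally resizing first.

    Values above 50% of the raster maximum become ``True``; ``fill_holes``
    additionally fills enclosed background for outline-style masks.
    """
    array = np.asarray(array)
    if array.ndim != 2:
        raise DimensionalityError(
            f"mask raster must be single-channel 2-D, got shape {array.shape}")
    if target_shape is not None:
        array = _nearest_resize(array, tuple(target_shape))
    maximum = array.max()
    if maximum <= 0:
        raise EmptyMaskError("mask raster is entirely black")
    region = array > 0.5 * maximum
    if fill_holes:
        region = ndimage.binary_fill_holes(region)
    return CellMask(region=region)


def load_mask(path: str | Path,
              target_shape: tuple[int, int],
              fill_holes: bool = False) -> CellMask:
    """Load a PNG (or any PIL-readable) mask and conform it to ``target_shape``."""
    path = Path(path)
    try:
        with Image.open(path) as img:
            if img.mode not in ("1", "L", "I", "I;16", "F"):
                img = img.convert("L")
            array = np.asarray(img)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ImageIOError(f"cannot read mask file {path}: {exc}") from exc
    return mask_from_array(array, target_shape=target_shape, fill_holes=fill_holes)
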