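"""Reading and writing the raster products of the imaging pipeline.

Scanner-side software exports each coronal slice as plain 8-bit rasters
(greyscale density and speed maps, an RGB axial-direction map).  Physical
calibration is never trusted from file metadata — the export format does
not specify it — and must be supplied by the caller (2 µm/pixel for the
super-resolution products by default).

TIFF is the primary interchange format (via :mod:`tifffile`); PNG is
accepted for convenience (via Pillow).  ROI label maps travel as 16-bit
TIFF with a JSON sidecar mapping label integers to region names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .maps import BinaryMask, IntensityMap, RegionSet, ThicknessMap

DEFAULT_PIXEL_SIZE_UM = 2.0


def _load_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path)
    return np.asarray(Image.open(path))


def read_raster(
    path: str | Path,
    modality: str,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> IntensityMap:
    """Read an 8-bit exported raster and attach physical calibration.

    Raises ``ValueError`` for non-8-bit input, or when the channel layout
    does not match the modality (speed/density must be greyscale, the
    directional map must be RGB).
    """
    path = Path(path)
    arr = _load_array(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit raster, got {arr.dtype}")
    if modality == "directional":
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise ValueError(f"{path}: directional map must be RGB")
        arr = arr[:, :, :3]  # drop an alpha channel if present
    else:
        if arr.ndim != 2:
            raise ValueError(f"{path}: {modality} map must be single-channel")
    return IntensityMap(values=arr, pixel_size_um=pixel_size_um, modality=modality)


def write_raster(path: str | Path, imap: IntensityMap) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, imap.values)
    else:
        Image.fromarray(imap.values).save(path)


def read_mask(
    path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> BinaryMask:
    arr = _load_array(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel")
    return BinaryMask(values=arr > 0, pixel_size_um=pixel_size_um)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(Path(path), mask.values.astype(np.uint8) * 255)


def read_regions(
    path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> RegionSet:
    """Read a 16-bit label TIFF plus its ``<stem>.json`` name table."""
    path = Path(path)
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise ValueError(f"{path}: label raster must be 2-D")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing label name table {sidecar}")
    table = {int(k): str(v) for k, v in json.loads(sidecar.read_text()).items()}
    return RegionSet(
        labels=labels.astype(np.int32), name_table=table, pixel_size_um=pixel_size_um
    )


def write_regions(path: str | Path, regions: RegionSet) -> None:
    path = Path(path)
    tifffile.imwrite(path, regions.labels.astype(np.uint16))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({str(k): v for k, v in regions.name_table.items()}, indent=2)
    )


def read_thickness(
    path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> ThicknessMap:
    values = tifffile.imread(Path(path))
    if values.ndim != 2:
        raise ValueError(f"{path}: thickness map must be 2-D")
    return ThicknessMap(values=np.asarray(values, dtype=float),
                        pixel_size_um=pixel_size_um)


def write_thickness(path: str | Path, tmap: ThicknessMap) -> None:
    """Thickness maps are written as 32-bit float TIFF in µm."""
    tifffile.imwrite(Path(path), tmap.values.astype(np.float32))


def write_float_map(path: str | Path, values: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))
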