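"""Core in-memory containers for calibrated raster products.

Every exported modality (vascular density, microbubble speed, axial flow
direction) arrives as an 8-bit raster with a known physical pixel size.
These containers keep the pixel grid and its calibration together so that
downstream morphometry and flow estimation can report physical units
(µm, mm/s, mL/min) instead of pixel counts.

Coordinate convention: row-major image coordinates, row index increasing
downward.  "Descending" axial flow therefore means flow toward larger row
indices, which for a coronal slice with the cortical surface at the top
corresponds to penetrating arterioles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("density", "speed", "directional")

#: region names understood by the band layouts and the pipeline
KNOWN_REGIONS = ("whole_brain", "cortex", "hippocampus", "white_matter")

WHOLE_BRAIN = "whole_brain"


@dataclass
class IntensityMap:
    """8-bit raster with physical calibration.

    ``values`` is a 2-D uint8 array for greyscale modalities (density,
    speed) or an (H, W, 3) uint8 array for the RGB directional export.
    """

    values: np.ndarray
    pixel_size_um: float
    modality: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.dtype != np.uint8:
            raise ValueError(
                f"{self.modality} map must be 8-bit, got {self.values.dtype}"
            )
        if self.modality == "directional":
            if self.values.ndim != 3 or self.values.shape[2] != 3:
                raise ValueError("directional map must be an RGB (H, W, 3) raster")
        else:
            if self.values.ndim != 2:
                raise ValueError(
                    f"{self.modality} map must be a 2-D greyscale raster, "
                    f"got shape {self.values.shape}"
                )
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


@dataclass
class BinaryMask:
    """Boolean vessel mask sharing the source raster's grid and calibration."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RegionSet:
    """Anatomical ROI labels on the image grid.

    ``labels`` assigns each pixel at most one named region (0 = unlabeled).
    ``whole_brain`` is treated as the union of all labeled pixels, so it is
    always a superset of every named region and never needs its own label.
    """

    labels: np.ndarray
    name_table: dict[int, str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label raster must be integer-typed")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        present = set(np.unique(self.labels)) - {0}
        declared = set(self.name_table)
        if 0 in declared:
            raise ValueError("label 0 is reserved for unlabeled pixels")
        missing = declared - present
        if missing:
            raise ValueError(f"labels {sorted(missing)} never occur in the raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def names(self) -> list[str]:
        out = [WHOLE_BRAIN]
        out.extend(n for n in self.name_table.values() if n != WHOLE_BRAIN)
        return out

    def mask(self, name: str) -> np.ndarray:
        """Boolean membership mask for a named region."""
        if name == WHOLE_BRAIN:
            return self.labels > 0
        for lab, nm in self.name_table.items():
            if nm == name:
                return self.labels == lab
        raise KeyError(f"unknown region {name!r}; have {self.names()}")

    def pixel_count(self, name: str) -> int:
        return int(self.mask(name).sum())


def select_region(values: np.ndarray, regions: RegionSet, name: str) -> np.ndarray:
    """Return the 1-D array of pixel values inside a named region.

    ``values`` may be any per-pixel array (intensity, thickness, speed,
    flow) on the same grid as ``regions``.
    """
    values = np.asarray(values)
    if values.shape[:2] != regions.shape:
        raise ValueError(
            f"shape mismatch: values {values.shape[:2]} vs regions {regions.shape}"
        )
    return values[regions.mask(name)]


@dataclass
class ThicknessMap:
    """Per-pixel vessel diameter (local thickness) in µm; 0 on background.

    ``unreliable`` flags pixels whose diameter falls below twice the
    reliability floor radius; such pixels stay in the map but are excluded
    from distributions and flow summaries by default.
    """

    values: np.ndarray
    pixel_size_um: float
    reliability_floor_radius_um: float | None = None
    unreliable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("thickness map must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("thickness values must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.unreliable is not None:
            self.unreliable = np.asarray(self.unreliable, dtype=bool)
            if self.unreliable.shape != self.values.shape:
                raise ValueError("flag raster must match the thickness grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.values > 0

    def reliable_foreground(self) -> np.ndarray:
        """Vessel pixels that survive the reliability filter."""
        fg = self.foreground
        if self.unreliable is None:
            return fg
        return fg & ~self.unreliable


@dataclass
class SpeedMap:
    """Per-pixel blood speed in mm/s, decoded from the 8-bit export."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("speed map must be 2-D")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("speeds must lie in [0, 100] mm/s")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FlowMap:
    """Per-pixel volumetric flow Q in mL/min.

    ``eligible`` marks the pixels on which Q was actually evaluated
    (vessel-positive, unflagged thickness); everywhere else Q is 0.
    """

    values: np.ndarray
    pixel_size_um: float
    eligible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("flow map must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("flow values must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.eligible is None:
            self.eligible = self.values > 0
        else:
            self.eligible = np.asarray(self.eligible, dtype=bool)
            if self.eligible.shape != self.values.shape:
                raise ValueError("eligibility raster must match the flow grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


# per-pixel direction classes
DIRECTION_NONE = 0
DIRECTION_ARTERIOLE = 1  # descending axial flow (toward larger row index)
DIRECTION_VENULE = 2  # ascending axial flow


@dataclass
class DirectionalMap:
    """Per-pixel arteriole/venule/none classification."""

    classes: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("directional class map must be 2-D")
        valid = np.isin(
            self.classes, (DIRECTION_NONE, DIRECTION_ARTERIOLE, DIRECTION_VENULE)
        )
        if not valid.all():
            raise ValueError("class values must be in {0, 1, 2}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape


@dataclass
class Histogram:
    """Normalized pixelwise histogram (relative frequencies sum to 1)."""

    bin_edges: np.ndarray
    relative_frequency: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.relative_frequency = np.asarray(self.relative_frequency, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.relative_frequency.size != self.bin_edges.size - 1:
            raise ValueError("need one frequency per bin")
        if np.any(self.relative_frequency < 0):
            raise ValueError("frequencies must be nonnegative")
        if self.n > 0 and abs(self.relative_frequency.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
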