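"""Speed decoding and Poiseuille-derived volumetric flow (resting CBF).

The exported speed map encodes microbubble speed 0–100 mm/s linearly into
the 8-bit range, so decoding divides the grey value by 2.55.  Volumetric
flow per pixel follows the simplified Poiseuille relation

    Q = v * A = v * pi * r^2 * K

with v the pixel's speed in mm/s, r the local vessel radius in µm (half
the local thickness), and K = 6e-8 the unit conversion placing Q in
mL/min: (1 mm/s)*(1 µm^2) = 1e-15 m^3/s = 6e-8 mL/min.

Regional resting CBF is summarized as the mean Q over vessel-positive,
reliability-filtered pixels of an ROI (an all-pixel average, which weights
the summary by vascular density, is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import (
    BinaryMask,
    FlowMap,
    Histogram,
    IntensityMap,
    RegionSet,
    SpeedMap,
    ThicknessMap,
)

#: (mm/s * µm^2) -> mL/min
K_ML_PER_MIN = 6e-8
MAX_SPEED_MM_S = 100.0
GREY_DIVISOR = 255.0 / MAX_SPEED_MM_S  # 2.55


@dataclass(frozen=True)
class FlowModelParams:
    """Constants of the speed encoding and the flow conversion."""

    K: float = K_ML_PER_MIN
    max_speed_mm_s: float = MAX_SPEED_MM_S
    grey_divisor: float = GREY_DIVISOR
    floor_radius_um: float = 5.0

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError("K must be positive")
        if abs(self.grey_divisor - 255.0 / self.max_speed_mm_s) > 1e-12:
            raise ValueError("grey_divisor must equal 255 / max_speed_mm_s")


def decode_speed(
    imap: IntensityMap, params: FlowModelParams = FlowModelParams()
) -> SpeedMap:
    """Convert an 8-bit speed raster to mm/s (grey value / 2.55)."""
    if imap.modality == "directional":
        raise ValueError("decode_speed expects a greyscale speed map, not RGB")
    v = imap.values.astype(float) / params.grey_divisor
    # 8-bit input cannot exceed full scale, but clip defensively
    np.clip(v, 0.0, params.max_speed_mm_s, out=v)
    return SpeedMap(values=v, pixel_size_um=imap.pixel_size_um)


def encode_speed(v_mm_s: np.ndarray, params: FlowModelParams = FlowModelParams()) -> np.ndarray:
    """Inverse of :func:`decode_speed`: mm/s -> rounded 8-bit grey values."""
    v = np.asarray(v_mm_s, dtype=float)
    if np.any(v < 0) or np.any(v > params.max_speed_mm_s):
        raise ValueError(f"velocities must lie in [0, {params.max_speed_mm_s}] mm/s")
    return np.clip(np.rint(v * params.grey_divisor), 0, 255).astype(np.uint8)


def flow_rate(
    v_mm_s: float | np.ndarray,
    diameter_um: float | np.ndarray,
    params: FlowModelParams = FlowModelParams(),
) -> float | np.ndarray:
    """Q = v * pi * (d/2)^2 * K, in mL/min (vectorized)."""
    v = np.asarray(v_mm_s, dtype=float)
    d = np.asarray(diameter_um, dtype=float)
    if np.any(v < 0) or np.any(d < 0):
        raise ValueError("speed and diameter must be nonnegative")
    q = v * np.pi * (d / 2.0) ** 2 * params.K
    return float(q) if q.ndim == 0 else q


def flow_rate_map(
    speed: SpeedMap,
    tmap: ThicknessMap,
    params: FlowModelParams = FlowModelParams(),
    apply_floor: bool = True,
) -> FlowMap:
    """Per-pixel volumetric flow by fusing the speed and thickness maps.

    Pixels with zero thickness carry Q = 0; pixels flagged by the
    reliability floor contribute 0 when ``apply_floor`` is set (default).
    """
    if speed.shape != tmap.shape:
        raise ValueError(
            f"shape mismatch: speed {speed.shape} vs thickness {tmap.shape}"
        )
    if abs(speed.pixel_size_um - tmap.pixel_size_um) > 1e-9:
        raise ValueError("speed and thickness maps disagree on calibration")
    eligible = tmap.reliable_foreground() if apply_floor else tmap.foreground
    q = np.where(eligible, flow_rate(speed.values, tmap.values, params), 0.0)
    return FlowMap(values=q, pixel_size_um=speed.pixel_size_um, eligible=eligible)


def regional_cbf(
    fmap: FlowMap,
    mask: BinaryMask,
    regions: RegionSet,
    name: str,
    domain: str = "vessel",
) -> float:
    """Mean Q (mL/min) over a named region.

    ``domain='vessel'`` (default) averages over vessel-positive, unflagged
    pixels — Q is undefined off-vessel.  ``domain='all'`` averages over
    every region pixel, producing a density-weighted variant.
    """
    if fmap.shape != regions.shape or mask.shape != regions.shape:
        raise ValueError("flow map, mask and regions must share one grid")
    region = regions.mask(name)
    if domain == "vessel":
        sel = region & mask.values & fmap.eligible
    elif domain == "all":
        sel = region
    else:
        raise ValueError(f"unknown averaging domain {domain!r}")
    if not sel.any():
        raise ValueError(f"no eligible pixels in region {name!r}")
    return float(fmap.values[sel].mean())


def _normalized_hist(vals: np.ndarray, edges: np.ndarray) -> Histogram:
    counts, edges = np.histogram(vals, bins=edges)
    return Histogram(
        bin_edges=np.asarray(edges, dtype=float),
        relative_frequency=counts / counts.sum(),
        n=int(vals.size),
    )


def speed_distribution(
    speed: SpeedMap,
    mask: BinaryMask,
    regions: RegionSet,
    name: str,
    bin_width_mm_s: float = 2.0,
) -> Histogram:
    """Relative frequency of pixel speeds over vessel pixels in a region."""
    sel = regions.mask(name) & mask.values
    vals = speed.values[sel]
    if vals.size == 0:
        raise ValueError(f"no vessel pixels in region {name!r}")
    edges = np.arange(0.0, MAX_SPEED_MM_S + bin_width_mm_s, bin_width_mm_s)
    return _normalized_hist(vals, edges)


def flow_distribution(
    fmap: FlowMap,
    mask: BinaryMask,
    regions: RegionSet,
    name: str,
    n_bins: int = 40,
) -> Histogram:
    """Relative frequency of per-pixel Q in a region, on logarithmic bins.

    Q spans orders of magnitude across vessel calibers, so the bins are
    log-spaced between the smallest and largest positive values present.
    """
    sel = regions.mask(name) & mask.values & fmap.eligible
    vals = fmap.values[sel]
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError(f"no eligible flow pixels in region {name!r}")
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        hi = lo * (1 + 1e-9) + 1e-300
    edges = np.geomspace(lo, hi, n_bins + 1)
    edges[0] *= 1 - 1e-12
    edges[-1] *= 1 + 1e-12
    return _normalized_hist(vals, edges)
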