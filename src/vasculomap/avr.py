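"""Cortical arteriole-to-venule ratio (AVR) from axial-direction maps.

The scanner's directionality export colors each vessel pixel by the sign
of its axial (image-row) flow component: red for one sense, blue for the
other.  In the cortex penetrating arterioles dive down from the surface
while ascending venules drain upward, so with the cortical surface at the
top of a coronal image, descending (red) pixels are arteriolar and
ascending (blue) pixels are venular.  The AVR — the ratio of arteriole to
venule pixel counts in the cortex — is a structural biomarker of
cerebrovascular remodeling, analogous to the retinal AVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import (
    DIRECTION_ARTERIOLE,
    DIRECTION_NONE,
    DIRECTION_VENULE,
    DirectionalMap,
    IntensityMap,
    RegionSet,
)


@dataclass(frozen=True)
class AvrResult:
    arteriole_pixels: int
    venule_pixels: int
    total_vascular_pixels: int
    avr: float
    arteriole_pct_of_total: float
    venule_pct_of_total: float


def classify_direction(
    imap: IntensityMap, red_is_arteriole: bool = True
) -> DirectionalMap:
    """Split an RGB direction map into arteriole/venule/none classes.

    A pixel is arteriolar when its red channel dominates blue (and is
    nonzero), venular when blue dominates red; exact ties and black pixels
    are 'none'.  ``red_is_arteriole=False`` swaps the convention for
    acquisitions with the opposite axis sign.
    """
    if imap.modality != "directional":
        raise ValueError("classify_direction expects an RGB directional map")
    red = imap.values[:, :, 0].astype(np.int16)
    blue = imap.values[:, :, 2].astype(np.int16)
    classes = np.full(red.shape, DIRECTION_NONE, dtype=np.int8)
    a, v = (DIRECTION_ARTERIOLE, DIRECTION_VENULE)
    if not red_is_arteriole:
        a, v = v, a
    classes[(red > blue) & (red > 0)] = a
    classes[(blue > red) & (blue > 0)] = v
    return DirectionalMap(classes=classes, pixel_size_um=imap.pixel_size_um)


def compute_avr(
    dmap: DirectionalMap, regions: RegionSet, name: str = "cortex"
) -> AvrResult:
    """Arteriole-to-venule pixel-count ratio within a named region.

    Restricted to the cortex by default: only there does the single-axis
    direction sensitivity align with vessel orientation well enough to
    separate the two populations.
    """
    if dmap.shape != regions.shape:
        raise ValueError("directional map and regions live on different grids")
    region = regions.mask(name)
    cls = dmap.classes[region]
    n_art = int((cls == DIRECTION_ARTERIOLE).sum())
    n_ven = int((cls == DIRECTION_VENULE).sum())
    if n_ven == 0:
        raise ValueError(f"no venule pixels in region {name!r}; AVR undefined")
    total = n_art + n_ven
    return AvrResult(
        arteriole_pixels=n_art,
        venule_pixels=n_ven,
        total_vascular_pixels=total,
        avr=n_art / n_ven,
        arteriole_pct_of_total=100.0 * n_art / total,
        venule_pct_of_total=100.0 * n_ven / total,
    )
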