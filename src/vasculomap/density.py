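"""Vascular coverage ("vascular density ratio") from binarized density maps.

The exported density map carries nonzero intensity wherever at least one
microbubble track crossed the pixel.  Binarizing at intensity >= 1 turns
every such pixel into vessel foreground; coverage of an ROI is then the
percentage of its pixels that are vessel-positive — the standard measure
of vascular rarefaction.
"""

from __future__ import annotations

import numpy as np

from .maps import BinaryMask, IntensityMap, RegionSet

#: any nonzero intensity counts as vessel signal
DEFAULT_THRESHOLD = 1


def binarize(imap: IntensityMap, threshold: int = DEFAULT_THRESHOLD) -> BinaryMask:
    """Threshold a greyscale density map into a vessel mask.

    A pixel is foreground iff its intensity is >= ``threshold``.  The
    default of 1 reproduces the convention that every colored (nonzero)
    pixel is vessel signal; raise it for sensitivity analyses.
    """
    if imap.modality == "directional":
        raise ValueError("binarize expects a greyscale density map, not RGB")
    return BinaryMask(values=imap.values >= threshold, pixel_size_um=imap.pixel_size_um)


def coverage(mask: BinaryMask, regions: RegionSet, name: str) -> float:
    """Percentage of vessel-positive pixels within a named region."""
    if mask.shape != regions.shape:
        raise ValueError(
            f"shape mismatch: mask {mask.shape} vs regions {regions.shape}"
        )
    region = regions.mask(name)
    total = int(region.sum())
    if total == 0:
        raise ValueError(f"region {name!r} contains no pixels; coverage undefined")
    positive = int((mask.values & region).sum())
    return 100.0 * positive / total


def coverage_table(mask: BinaryMask, regions: RegionSet) -> dict[str, float]:
    """Coverage for every region in the set (including whole_brain)."""
    return {name: coverage(mask, regions, name) for name in regions.names()}
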