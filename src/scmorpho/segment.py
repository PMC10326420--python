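"""Connected lumen components and the SC part-selection rule.

A Schlemm's canal (SC) segmentation arrives as a stack of per-B-scan binary
masks.  This module extracts 8-connected foreground components per B-scan,
computes their areas and central second moments in physical (micron)
coordinates, and applies the SC selection rule: within one cross-section the
anchor is the largest connected lumen (optionally restricted to a region of
interest standing in for "immediately lateral to the iridocorneal angle"),
and every part with area at least 20% of the anchor's is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskStack",
    "LumenComponent",
    "Roi",
    "extract_components",
    "select_sc_components",
]

# 8-connectivity: diagonal contact joins thin lumen fragments.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Roi:
    """Rectangular pixel-bound region of interest (inclusive bounds).

    Encodes the anatomical criterion "immediately lateral to the iridocorneal
    angle" declaratively: components whose centroid falls outside the
    rectangle are never selected.  Bounds are in pixels, ``lateral`` along
    columns and ``axial`` along rows.
    """

    lateral_min_px: float
    lateral_max_px: float
    axial_min_px: float
    axial_max_px: float

    def contains(self, lateral_px: float, axial_px: float) -> bool:
        return (
            self.lateral_min_px <= lateral_px <= self.lateral_max_px
            and self.axial_min_px <= axial_px <= self.axial_max_px
        )


@dataclass
class MaskStack:
    """Ordered per-B-scan binary lumen masks with physical pixel calibration.

    Parameters
    ----------
    masks
        Boolean array of shape ``(n_bscans, n_axial_px, n_lateral_px)``.
        Rows are axial (depth), columns lateral.
    lateral_um_per_px, axial_um_per_px
        Pixel calibration in microns per pixel.
    bscan_spacing_um
        Physical distance between consecutive B-scans.
    roi
        Optional :class:`Roi` marking the expected SC neighbourhood.
    """

    masks: np.ndarray
    lateral_um_per_px: float
    axial_um_per_px: float
    bscan_spacing_um: float
    roi: Roi | None = None

    def __post_init__(self) -> None:
        masks = np.asarray(self.masks)
        if masks.ndim != 3:
            raise ValueError(
                f"masks must be a 3-D (n_bscans, rows, cols) array, got shape {masks.shape}"
            )
        self.masks = masks.astype(bool)
        for name in ("lateral_um_per_px", "axial_um_per_px", "bscan_spacing_um"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")

    @property
    def n_bscans(self) -> int:
        return self.masks.shape[0]

    def __len__(self) -> int:
        return self.n_bscans


@dataclass(eq=False)  # identity equality: components carry pixel arrays
class LumenComponent:
    """One 8-connected lumen part in one B-scan.

    Areas, centroids and central second moments are computed over pixel
    centers in physical micron coordinates (``lateral = col * lateral_um_per_px``,
    ``axial = row * axial_um_per_px``).  ``mu20``/``mu02``/``mu11`` are raw
    central moment sums (lateral/axial/mixed), i.e. ``mu20 = sum (x - xbar)^2``
    over foreground pixels.
    """

    bscan_index: int
    pixel_count: int
    area_um2: float
    centroid_lateral_um: float
    centroid_axial_um: float
    mu20: float
    mu02: float
    mu11: float
    lateral_um_per_px: float
    axial_um_per_px: float
    rows: np.ndarray = field(repr=False)
    cols: np.ndarray = field(repr=False)

    @property
    def centroid_lateral_px(self) -> float:
        return self.centroid_lateral_um / self.lateral_um_per_px

    @property
    def centroid_axial_px(self) -> float:
        return self.centroid_axial_um / self.axial_um_per_px


def extract_components(
    mask: np.ndarray,
    lateral_um_per_px: float,
    axial_um_per_px: float,
    bscan_index: int = 0,
) -> list[LumenComponent]:
    """Extract one :class:`LumenComponent` per 8-connected foreground region.

    An empty mask yields an empty list.  Moments are computed in physical
    micron coordinates so that the downstream moment-ellipse axes come out in
    microns even on the ~5x anisotropic OCT grid.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    labels, n = ndimage.label(mask != 0, structure=_STRUCTURE_8)
    pixel_area = lateral_um_per_px * axial_um_per_px
    out: list[LumenComponent] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        x = cols * lateral_um_per_px
        y = rows * axial_um_per_px
        xbar = float(x.mean())
        ybar = float(y.mean())
        dx = x - xbar
        dy = y - ybar
        out.append(
            LumenComponent(
                bscan_index=bscan_index,
                pixel_count=rows.size,
                area_um2=rows.size * pixel_area,
                centroid_lateral_um=xbar,
                centroid_axial_um=ybar,
                mu20=float(dx @ dx),
                mu02=float(dy @ dy),
                mu11=float(dx @ dy),
                lateral_um_per_px=lateral_um_per_px,
                axial_um_per_px=axial_um_per_px,
                rows=rows,
                cols=cols,
            )
        )
    return out


def select_sc_components(
    components: list[LumenComponent],
    roi: Roi | None = None,
    min_area_fraction: float = 0.20,
) -> list[LumenComponent]:
    """Apply the SC part-selection rule within one cross-section.

    The anchor is the largest-area component whose centroid lies inside
    ``roi`` (the whole frame when ``roi`` is None); the returned list holds
    every in-roi component whose area is at least ``min_area_fraction`` of
    the anchor's ("at least 20%" is read inclusively).  Empty input, or no
    component inside the roi, yields an empty list.
    """
    if roi is None:
        candidates = list(components)
    else:
        candidates = [
            c for c in components if roi.contains(c.centroid_lateral_px, c.centroid_axial_px)
        ]
    if not candidates:
        return []
    anchor_area = max(c.area_um2 for c in candidates)
    threshold = min_area_fraction * anchor_area
    return [c for c in candidates if c.area_um2 >= threshold]
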