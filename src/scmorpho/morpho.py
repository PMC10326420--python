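"""Per-cross-section and per-eye SC morphometrics.

The morphometric core is the equal-second-moment ellipse: for each selected
lumen component the ellipse sharing its normalized central second moments is
computed (with the per-axis +(pixel size)^2/12 finite-pixel correction), and

* SC *width* of a cross-section is the sum of the fitted major axes,
* SC *height* is the area-weighted mean of the fitted minor axes,
* SC *area* is the summed component area,
* SC *volume* over the analyzed length is the rectangle-rule integral of the
  per-section area along the B-scan axis.

Corrections are applied per axis in microns before the eigen-decomposition
because the lateral (~7 um) and axial (~1.3 um) pixel sizes differ ~5x;
an ellipse fitted in pixel space would have distorted axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segment import LumenComponent

__all__ = [
    "EllipseFit",
    "CrossSectionMorphometry",
    "SeriesSummary",
    "fit_ellipse",
    "cross_section_morphometry",
    "series_morphometry",
    "area_length_profile",
    "cornea_thickness",
    "sc_area_per_field",
]


@dataclass(frozen=True)
class EllipseFit:
    """Equal-second-moment ellipse of one lumen component (full axes, um)."""

    major_axis_um: float
    minor_axis_um: float
    orientation_rad: float
    component: LumenComponent


@dataclass(frozen=True)
class CrossSectionMorphometry:
    """SC morphometrics of one B-scan (empty sections carry NaN width/height)."""

    bscan_index: int
    area_um2: float
    width_um: float
    height_um: float
    n_components: int

    @property
    def empty(self) -> bool:
        return self.n_components == 0


@dataclass(frozen=True)
class SeriesSummary:
    """Aggregate morphometrics of one mask stack over the analysis window."""

    volume_um3: float
    mean_width_um: float
    mean_height_um: float
    mean_area_um2: float
    n_sections_analyzed: int
    n_nonempty_sections: int
    length_analyzed_um: float


def fit_ellipse(component: LumenComponent) -> EllipseFit:
    """Fit the ellipse with identical normalized second central moments.

    With ``uxx = mu20/n + s_lat^2/12``, ``uyy = mu02/n + s_ax^2/12`` and
    ``uxy = mu11/n`` (physical-unit normalized moments plus the per-axis
    pixel-extent correction), the full axes are

        major = 2*sqrt(2) * sqrt(uxx + uyy + common)
        minor = 2*sqrt(2) * sqrt(uxx + uyy - common)
        common = sqrt((uxx - uyy)^2 + 4*uxy^2)

    A single-pixel component returns the pixel-extent-corrected axes
    (2*s/sqrt(3) per axis), never zero.  Orientation is the angle of the
    major axis from the lateral axis, in radians, measured in the
    (lateral, axial-down) image frame.
    """
    if component.pixel_count < 1:
        raise ValueError("cannot fit an ellipse to an empty component")
    n = component.pixel_count
    uxx = component.mu20 / n + component.lateral_um_per_px**2 / 12.0
    uyy = component.mu02 / n + component.axial_um_per_px**2 / 12.0
    uxy = component.mu11 / n
    common = math.sqrt((uxx - uyy) ** 2 + 4.0 * uxy**2)
    major = 2.0 * math.sqrt(2.0) * math.sqrt(uxx + uyy + common)
    minor = 2.0 * math.sqrt(2.0) * math.sqrt(max(uxx + uyy - common, 0.0))
    orientation = 0.5 * math.atan2(2.0 * uxy, uxx - uyy)
    return EllipseFit(
        major_axis_um=major,
        minor_axis_um=minor,
        orientation_rad=orientation,
        component=component,
    )


def cross_section_morphometry(
    fits: list[EllipseFit], bscan_index: int
) -> CrossSectionMorphometry:
    """Aggregate the selected parts of one B-scan.

    width = sum of major axes; height = area-weighted mean of minor axes;
    area = summed component area.  Empty input yields an empty-flagged record
    with area 0 and NaN width/height.
    """
    if not fits:
        return CrossSectionMorphometry(bscan_index, 0.0, math.nan, math.nan, 0)
    areas = np.array([f.component.area_um2 for f in fits])
    majors = np.array([f.major_axis_um for f in fits])
    minors = np.array([f.minor_axis_um for f in fits])
    total_area = float(areas.sum())
    return CrossSectionMorphometry(
        bscan_index=bscan_index,
        area_um2=total_area,
        width_um=float(majors.sum()),
        height_um=float((areas * minors).sum() / total_area),
        n_components=len(fits),
    )


def series_morphometry(
    sections: list[CrossSectionMorphometry],
    bscan_spacing_um: float,
    window_um: float = 1500.0,
) -> SeriesSummary:
    """Aggregate a stack over the first ``window_um`` of canal length.

    The window is anchored at the first analyzed B-scan: the first
    ``floor(window_um / spacing)`` sections enter the analysis (all of them
    if fewer).  Volume integrates area with the rectangle rule and counts
    empty sections as zero area; mean width/height/area average over
    non-empty sections only.  If every analyzed section is empty the volume
    is 0 and the means are NaN.
    """
    if len(sections) < 2:
        raise ValueError("series morphometry needs at least 2 cross-sections")
    if not bscan_spacing_um > 0:
        raise ValueError("bscan_spacing_um must be positive")
    n_window = int(math.floor(window_um / bscan_spacing_um))
    analyzed = sections[: max(n_window, 0)] if n_window < len(sections) else sections
    nonempty = [s for s in analyzed if not s.empty]
    volume = sum(s.area_um2 for s in analyzed) * bscan_spacing_um
    if nonempty:
        areas = np.array([s.area_um2 for s in nonempty])
        mean_width = float(np.mean([s.width_um for s in nonempty]))
        mean_height = float(np.mean([s.height_um for s in nonempty]))
        mean_area = float(areas.mean())
    else:
        mean_width = mean_height = mean_area = math.nan
    return SeriesSummary(
        volume_um3=float(volume),
        mean_width_um=mean_width,
        mean_height_um=mean_height,
        mean_area_um2=mean_area,
        n_sections_analyzed=len(analyzed),
        n_nonempty_sections=len(nonempty),
        length_analyzed_um=len(analyzed) * bscan_spacing_um,
    )


def area_length_profile(
    sections: list[CrossSectionMorphometry], bscan_spacing_um: float
) -> np.ndarray:
    """Ordered (length_um, area_um2) pairs along the canal, from the window start."""
    if not bscan_spacing_um > 0:
        raise ValueError("bscan_spacing_um must be positive")
    return np.array(
        [(i * bscan_spacing_um, s.area_um2) for i, s in enumerate(sections)], dtype=float
    )


def cornea_thickness(
    boundary_pairs: list[tuple[np.ndarray, np.ndarray]],
    axial_um_per_px: float,
) -> float:
    """Mean peripheral cornea thickness from anterior/posterior boundary pairs.

    Each cross-section supplies paired anterior and posterior axial pixel
    coordinates sampled over a shared lateral range; per-section thickness is
    the mean axial separation times the axial calibration, and the result is
    the mean over sections (three cross-sections per eye in practice).
    Raises if the boundaries cross (posterior above anterior anywhere).
    """
    if not boundary_pairs:
        raise ValueError("at least one cross-section boundary pair is required")
    per_section = []
    for i, (anterior, posterior) in enumerate(boundary_pairs):
        anterior = np.asarray(anterior, dtype=float)
        posterior = np.asarray(posterior, dtype=float)
        if anterior.shape != posterior.shape:
            raise ValueError(f"section {i}: boundary arrays differ in shape")
        sep = posterior - anterior
        if np.any(sep < 0):
            raise ValueError(f"section {i}: posterior boundary crosses above anterior")
        per_section.append(float(sep.mean()) * axial_um_per_px)
    return float(np.mean(per_section))


def sc_area_per_field(field_masks: list[np.ndarray], um_per_px: float) -> float:
    """Mean stained-SC area per high-power field (flat-mount quantification).

    Each mask is one 20X field; the returned value is the mean over fields of
    the foreground area in um^2 (fields are isotropic epifluorescence images,
    so one scalar calibration applies to both axes).
    """
    if not field_masks:
        raise ValueError("at least one high-power-field mask is required")
    pixel_area = um_per_px * um_per_px
    return float(np.mean([np.count_nonzero(m) * pixel_area for m in field_masks]))
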