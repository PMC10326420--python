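"""End-to-end measurement: mask stacks -> per-eye morphometry tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import morpho, segment
from .morpho import SeriesSummary
from .segment import MaskStack, Roi


def measure_stack(
    stack: MaskStack,
    roi: Roi | None = None,
    window_um: float = 1500.0,
) -> tuple[pd.DataFrame, SeriesSummary]:
    """Run component extraction, selection and morphometry on one stack.

    Returns the per-cross-section table (bscan_index, area_um2, width_um,
    height_um, n_components, empty) and the windowed series summary.
    """
    roi = roi if roi is not None else stack.roi
    sections = []
    for i, mask in enumerate(stack.masks):
        components = segment.extract_components(
            mask, stack.lateral_um_per_px, stack.axial_um_per_px, bscan_index=i
        )
        selected = segment.select_sc_components(components, roi)
        fits = [morpho.fit_ellipse(c) for c in selected]
        sections.append(morpho.cross_section_morphometry(fits, i))
    summary = morpho.series_morphometry(sections, stack.bscan_spacing_um, window_um)
    table = pd.DataFrame(
        {
            "bscan_index": [s.bscan_index for s in sections],
            "area_um2": [s.area_um2 for s in sections],
            "width_um": [s.width_um for s in sections],
            "height_um": [s.height_um for s in sections],
            "n_components": [s.n_components for s in sections],
            "empty": [s.empty for s in sections],
        }
    )
    return table, summary


def _summary_row(meta: dict, summary: SeriesSummary) -> dict:
    return {
        **meta,
        "volume_um3": summary.volume_um3,
        "mean_width_um": summary.mean_width_um,
        "mean_height_um": summary.mean_height_um,
        "mean_area_um2": summary.mean_area_um2,
        "n_nonempty_sections": summary.n_nonempty_sections,
        "length_analyzed_um": summary.length_analyzed_um,
    }


def measure_experiment(
    manifest: pd.DataFrame | str | Path,
    base_dir: str | Path | None = None,
    window_um: float = 1500.0,
) -> pd.DataFrame:
    """Measure every stack listed in a manifest.

    ``manifest`` is the table (or CSV path) with columns eye_id, group,
    delta_iop_mmHg, repeat, stack_path; relative stack paths resolve against
    ``base_dir`` (defaulting to the manifest's directory).  Returns one
    eye-measurement row per manifest row.
    """
    from .phantom import read_mask_stack

    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        if base_dir is None:
            base_dir = manifest_path.parent
        manifest = pd.read_csv(manifest_path)
    base_dir = Path(base_dir) if base_dir is not None else Path(".")
    rows = []
    for rec in manifest.to_dict("records"):
        stack = read_mask_stack(base_dir / rec["stack_path"])
        roi = None
        if {"roi_lat_min", "roi_lat_max", "roi_ax_min", "roi_ax_max"} <= set(rec):
            roi = Roi(
                rec["roi_lat_min"], rec["roi_lat_max"], rec["roi_ax_min"], rec["roi_ax_max"]
            )
        _, summary = measure_stack(stack, roi=roi, window_um=window_um)
        meta = {
            k: rec[k] for k in ("eye_id", "group", "delta_iop_mmHg", "repeat") if k in rec
        }
        rows.append(_summary_row(meta, summary))
    return pd.DataFrame(rows)


def measure_experiment_arrays(design, seed: int = 0, window_um: float = 1500.0) -> pd.DataFrame:
    """Generate a phantom experiment in memory and measure it in one pass.

    Disk-free counterpart of ``phantom.generate_experiment`` followed by
    :func:`measure_experiment`; used by the Monte-Carlo benchmarks.
    """
    from .phantom import iter_experiment

    rows = []
    for group, eye_id, level, rep, stack, _truth, _scale in iter_experiment(design, seed):
        _, summary = measure_stack(stack, window_um=window_um)
        meta = {"eye_id": eye_id, "group": group, "delta_iop_mmHg": level, "repeat": rep}
        rows.append(_summary_row(meta, summary))
    return pd.DataFrame(rows)
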