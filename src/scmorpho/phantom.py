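"""Synthetic SC-lumen phantom with exact analytic ground truth.

No raw anterior-segment OCT data accompany the study this pipeline targets,
so validation is closed-loop: this module generates stacks of binary
B-scan masks of an elliptical Schlemm's-canal lumen whose geometry responds
linearly to an imposed IOP offset, together with the analytic truth
(area, width, height, volume and the generating slopes) that the analysis
side must recover.

Deformation model
-----------------
Height deforms linearly, ``h(d) = height0 + slope_height * d`` (d = IOP
offset in mmHg), and cross-sectional area is ``A(d) = pi/4 * width0 * h(d) *
(1 + slope_area_frac * d)``; the effective lumen width is ``w(d) = width0 *
(1 + slope_area_frac * d)`` so that the moment-ellipse of the raster
recovers both axes.  With ``slope_area_frac = 0`` the width is constant and
all area change rides on height.

Septation splits a cross-section into two side-by-side sub-ellipses with
full widths ``r*w`` and ``(1-r)*w`` and the same height, which conserves the
analytic area, summed width and area-weighted height exactly.

Noise has two realistic components: smooth radial boundary jitter of SD
``noise_px`` pixels per B-scan (segmentation-trace variability), and a
per-acquisition scale factor of SD ``repeat_noise_frac`` applied to the
lumen height (repeat-to-repeat measurement variability).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segment import MaskStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "IOPExperimentDesign",
    "PhantomError",
    "generate_mask_stack",
    "generate_experiment",
    "iter_experiment",
    "control_spec",
    "mutant_spec",
    "default_study_design",
    "write_mask_stack",
    "read_mask_stack",
]

#: IOP offsets from baseline used in the in-vivo protocol (mmHg).
DEFAULT_DELTA_IOP_LEVELS = (-10.0, -5.0, 0.0, 5.0, 10.0)

_HARMONICS = 6  # boundary-jitter Fourier harmonics


class PhantomError(ValueError):
    """Invalid phantom specification or infeasible generation request."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic SC lumen.

    Defaults follow the imaging geometry of the anterior-segment vis-OCT
    system this emulates: 7 um lateral and 1.3 um axial pixels, a 1.5 mm
    segmented canal length, and lumen axes of a few hundred by a few tens
    of microns.
    """

    length_um: float = 1500.0
    n_bscans: int = 50
    width0_um: float = 200.0
    height0_um: float = 25.0
    slope_height_um_per_mmHg: float = 0.0
    slope_area_frac_per_mmHg: float = 0.0
    septa_stations: tuple[tuple[int, int, float], ...] = ()
    lateral_um_per_px: float = 7.0
    axial_um_per_px: float = 1.3
    noise_px: float = 0.0
    repeat_noise_frac: float = 0.0
    grid_shape: tuple[int, int] | None = None  # (rows, cols); auto-sized if None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width0_um > 0 or not self.height0_um > 0:
            raise PhantomError("width0_um and height0_um must be positive")
        if self.n_bscans < 2:
            raise PhantomError("n_bscans must be at least 2")
        if not (self.lateral_um_per_px > 0 and self.axial_um_per_px > 0):
            raise PhantomError("pixel sizes must be positive")
        if not self.length_um > 0:
            raise PhantomError("length_um must be positive")
        if self.noise_px < 0 or self.repeat_noise_frac < 0:
            raise PhantomError("noise amplitudes must be non-negative")
        for s in self.septa_stations:
            if len(s) != 3:
                raise PhantomError("each septa station is (start, end, area_ratio)")
            start, end, ratio = s
            if not 0 < ratio < 1:
                raise PhantomError(f"septa area ratio must be in (0, 1), got {ratio}")
            if not 0 <= start < end <= self.n_bscans:
                raise PhantomError(f"septa station ({start}, {end}) out of range")

    @property
    def bscan_spacing_um(self) -> float:
        return self.length_um / self.n_bscans

    def deformed(self, delta_iop: float) -> tuple[float, float]:
        """Analytic (width_um, height_um) at an IOP offset; fails if collapsed."""
        h = self.height0_um + self.slope_height_um_per_mmHg * delta_iop
        if not h > 0:
            raise PhantomError(
                f"deformed height {h:.3g} um is not positive at delta IOP "
                f"{delta_iop:+g} mmHg"
            )
        w = self.width0_um * (1.0 + self.slope_area_frac_per_mmHg * delta_iop)
        if not w > 0:
            raise PhantomError(
                f"deformed width {w:.3g} um is not positive at delta IOP "
                f"{delta_iop:+g} mmHg"
            )
        return w, h

    def septum_ratio(self, bscan_index: int) -> float | None:
        """Area ratio of the first sub-lumen if this B-scan is septated."""
        for start, end, ratio in self.septa_stations:
            if start <= bscan_index < end:
                return ratio
        return None


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one stack: geometry at its IOP offset plus slopes."""

    delta_iop_mmHg: float
    area_um2: float
    width_um: float
    height_um: float
    volume_um3: float
    slope_height_um_per_mmHg: float
    slope_area_frac_per_mmHg: float


@dataclass(frozen=True)
class IOPExperimentDesign:
    """Design of one clamped-IOP imaging experiment.

    Each group carries its own :class:`PhantomSpec`; every eye in a group
    shares the group spec up to a per-eye size factor drawn once per eye
    (``eye_scale_sd`` fractional SD on the baseline width, emulating
    between-animal canal size variation).
    """

    groups: tuple[tuple[str, PhantomSpec], ...]
    delta_iop_levels_mmHg: tuple[float, ...] = DEFAULT_DELTA_IOP_LEVELS
    repeats_per_level: int = 3
    eyes_per_group: int = 1
    eye_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.repeats_per_level < 1:
            raise PhantomError("repeats_per_level must be >= 1")
        if self.eyes_per_group < 1:
            raise PhantomError("eyes_per_group must be >= 1")
        if len(set(self.delta_iop_levels_mmHg)) != len(self.delta_iop_levels_mmHg):
            raise PhantomError("delta IOP levels must be distinct")
        if not self.groups:
            raise PhantomError("at least one group is required")
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise PhantomError("group labels must be unique")


def _smooth_periodic_noise(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean periodic field with approximately unit SD over theta."""
    ks = np.arange(1, _HARMONICS + 1)
    weights = (1.0 / ks) / math.sqrt(2.0 * float(np.sum(1.0 / ks**2)))
    a = rng.standard_normal(_HARMONICS)
    b = rng.standard_normal(_HARMONICS)
    kt = np.multiply.outer(theta, ks)  # (..., K)
    return (np.cos(kt) * (a * weights) + np.sin(kt) * (b * weights)).sum(axis=-1)


def _raster_ellipse(
    grid_x: np.ndarray,
    grid_y: np.ndarray,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    noise_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pixel-center-inside rasterization of one (jittered) ellipse."""
    a, b = semi_axes
    dx = (grid_x - center[0]) / a
    dy = (grid_y - center[1]) / b
    u = np.sqrt(dx * dx + dy * dy)
    if noise_um <= 0:
        return u <= 1.0
    theta = np.arctan2(dy, dx)
    rho = np.sqrt((a * np.cos(theta)) ** 2 + (b * np.sin(theta)) ** 2)
    jitter = noise_um * _smooth_periodic_noise(theta, rng)
    return u <= 1.0 + jitter / rho


def _grid_for(spec: PhantomSpec, max_width_um: float, max_height_um: float):
    """Choose (rows, cols) and grid center holding the worst-case lumen."""
    gap_um = 3.0 * spec.lateral_um_per_px if spec.septa_stations else 0.0
    noise_um = spec.noise_px * math.sqrt(spec.lateral_um_per_px * spec.axial_um_per_px)
    pad_um = 5.0 * noise_um + 3.0 * max(spec.lateral_um_per_px, spec.axial_um_per_px)
    need_lat = max_width_um + gap_um + 2.0 * pad_um
    need_ax = max_height_um + 2.0 * pad_um
    cols = int(math.ceil(need_lat / spec.lateral_um_per_px)) + 1
    rows = int(math.ceil(need_ax / spec.axial_um_per_px)) + 1
    if spec.grid_shape is not None:
        grows, gcols = spec.grid_shape
        if grows < rows or gcols < cols:
            raise PhantomError(
                f"grid_shape {spec.grid_shape} too small to contain the lumen; "
                f"needs at least ({rows}, {cols})"
            )
        rows, cols = grows, gcols
    return rows, cols


def generate_mask_stack(
    spec: PhantomSpec,
    delta_iop: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[MaskStack, GroundTruth]:
    """Rasterize one stack of B-scan masks at one IOP offset.

    The ground truth is computed analytically from ``spec`` (never from the
    raster): noise -- boundary jitter and the per-acquisition scale factor --
    perturbs only the masks.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        spec.seed if seed is None else seed
    )
    width, height = spec.deformed(delta_iop)
    area = math.pi / 4.0 * width * height
    truth = GroundTruth(
        delta_iop_mmHg=float(delta_iop),
        area_um2=area,
        width_um=width,
        height_um=height,
        volume_um3=area * spec.length_um,
        slope_height_um_per_mmHg=spec.slope_height_um_per_mmHg,
        slope_area_frac_per_mmHg=spec.slope_area_frac_per_mmHg,
    )
    # per-acquisition scale noise on height (scales area/volume by the same factor)
    scale = 1.0
    if spec.repeat_noise_frac > 0:
        scale = max(1.0 + spec.repeat_noise_frac * float(rng.standard_normal()), 0.2)
    h_real = height * scale

    rows, cols = _grid_for(spec, width, h_real)
    cx = (cols - 1) / 2.0 * spec.lateral_um_per_px
    cy = (rows - 1) / 2.0 * spec.axial_um_per_px
    x = np.arange(cols) * spec.lateral_um_per_px
    y = np.arange(rows) * spec.axial_um_per_px
    grid_x, grid_y = np.meshgrid(x, y)
    noise_um = spec.noise_px * math.sqrt(spec.lateral_um_per_px * spec.axial_um_per_px)
    gap_um = 3.0 * spec.lateral_um_per_px

    masks = np.zeros((spec.n_bscans, rows, cols), dtype=bool)
    for i in range(spec.n_bscans):
        ratio = spec.septum_ratio(i)
        if ratio is None:
            masks[i] = _raster_ellipse(
                grid_x, grid_y, (cx, cy), (width / 2.0, h_real / 2.0), noise_um, rng
            )
        else:
            w1, w2 = ratio * width, (1.0 - ratio) * width
            total = width + gap_um
            c1 = cx - total / 2.0 + w1 / 2.0
            c2 = cx + total / 2.0 - w2 / 2.0
            m1 = _raster_ellipse(
                grid_x, grid_y, (c1, cy), (w1 / 2.0, h_real / 2.0), noise_um, rng
            )
            m2 = _raster_ellipse(
                grid_x, grid_y, (c2, cy), (w2 / 2.0, h_real / 2.0), noise_um, rng
            )
            masks[i] = m1 | m2
    stack = MaskStack(
        masks=masks,
        lateral_um_per_px=spec.lateral_um_per_px,
        axial_um_per_px=spec.axial_um_per_px,
        bscan_spacing_um=spec.bscan_spacing_um,
    )
    return stack, truth


def iter_experiment(design: IOPExperimentDesign, seed: int = 0):
    """Yield (group, eye_id, delta_iop, repeat, MaskStack, GroundTruth, eye_scale).

    All randomness derives deterministically from ``seed``: eye scale factors
    and per-stack RNG streams are spawned from one seed sequence in a fixed
    order, so the same seed reproduces the experiment exactly.
    """
    yield from _iter_experiment_impl(design, np.random.SeedSequence(seed))


def _iter_experiment_impl(design: IOPExperimentDesign, root: np.random.SeedSequence):
    children = iter(root.spawn(
        len(design.groups)
        * design.eyes_per_group
        * (1 + len(design.delta_iop_levels_mmHg) * design.repeats_per_level)
    ))
    for group_label, spec in design.groups:
        for eye in range(design.eyes_per_group):
            eye_id = f"{group_label}_eye{eye + 1:02d}"
            eye_rng = np.random.default_rng(next(children))
            scale = 1.0
            if design.eye_scale_sd > 0:
                scale = max(1.0 + design.eye_scale_sd * float(eye_rng.standard_normal()), 0.3)
            eye_spec = replace(spec, width0_um=spec.width0_um * scale)
            for level in design.delta_iop_levels_mmHg:
                for rep in range(1, design.repeats_per_level + 1):
                    stack_rng = np.random.default_rng(next(children))
                    stack, truth = generate_mask_stack(eye_spec, level, stack_rng)
                    yield group_label, eye_id, float(level), rep, stack, truth, scale


def _stack_filename(eye_id: str, level: float, rep: int) -> str:
    tag = f"m{abs(level):g}" if level < 0 else f"p{level:g}"
    return f"{eye_id}_iop{tag}_rep{rep}.tif"


def write_mask_stack(stack: MaskStack, path: str | Path) -> Path:
    """Write a stack as 8-bit (0/255) multi-page TIFF plus a calibration sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, (stack.masks.astype(np.uint8) * 255), photometric="minisblack"
    )
    sidecar = {
        "lateral_um_per_px": stack.lateral_um_per_px,
        "axial_um_per_px": stack.axial_um_per_px,
        "bscan_spacing_um": stack.bscan_spacing_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_mask_stack(path: str | Path, calibration: dict | None = None) -> MaskStack:
    """Read a mask stack written by :func:`write_mask_stack` (or compatible).

    ``path`` may be a multi-page TIFF (with a sidecar ``<stem>.json`` holding
    the calibration) or a directory of single-page PNG/TIFF images ordered by
    zero-padded filename.  An explicit ``calibration`` dict overrides the
    sidecar; a missing calibration is a configuration error, mixed page
    shapes a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        import imageio.v3 as iio

        pages = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if len(pages) < 2:
            raise ValueError(f"{path}: a mask stack needs at least 2 pages")
        arrays = [np.asarray(iio.imread(p)) for p in pages]
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"{path}: pages differ in raster shape: {sorted(shapes)}")
        masks = np.stack(arrays)
        sidecar_path = path / "calibration.json"
    else:
        with tifffile.TiffFile(path) as tif:
            arrays = [page.asarray() for page in tif.pages]
        if len(arrays) < 2:
            raise ValueError(f"{path}: a mask stack needs at least 2 pages")
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise ValueError(f"{path}: pages differ in raster shape: {sorted(shapes)}")
        masks = np.stack(arrays)
        sidecar_path = path.with_suffix(".json")
    if calibration is None:
        if not sidecar_path.exists():
            raise ValueError(
                f"{path}: no calibration given and sidecar {sidecar_path.name} not found"
            )
        calibration = json.loads(sidecar_path.read_text())
    missing = {"lateral_um_per_px", "axial_um_per_px", "bscan_spacing_um"} - set(calibration)
    if missing:
        raise ValueError(f"{path}: calibration missing keys {sorted(missing)}")
    return MaskStack(
        masks=masks != 0,
        lateral_um_per_px=float(calibration["lateral_um_per_px"]),
        axial_um_per_px=float(calibration["axial_um_per_px"]),
        bscan_spacing_um=float(calibration["bscan_spacing_um"]),
    )


def generate_experiment(
    design: IOPExperimentDesign, out_dir: str | Path, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write one stack per (group, eye, level, repeat) plus manifest and truth.

    Returns the manifest and ground-truth tables; both are also written as
    ``manifest.csv`` and ``ground_truth.csv`` under ``out_dir``.  Repeats of
    one (eye, level) differ only by noise realization; the whole experiment
    is reproduced exactly by the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    for group, eye_id, level, rep, stack, truth, _scale in iter_experiment(design, seed):
        fname = _stack_filename(eye_id, level, rep)
        write_mask_stack(stack, out_dir / fname)
        manifest_rows.append(
            {
                "eye_id": eye_id,
                "group": group,
                "delta_iop_mmHg": level,
                "repeat": rep,
                "stack_path": fname,
            }
        )
        truth_rows.append(
            {
                "eye_id": eye_id,
                "group": group,
                "delta_iop_mmHg": level,
                "repeat": rep,
                "true_area_um2": truth.area_um2,
                "true_width_um": truth.width_um,
                "true_height_um": truth.height_um,
                "true_volume_um3": truth.volume_um3,
                "true_slope_height_um_per_mmHg": truth.slope_height_um_per_mmHg,
                "true_slope_area_frac_per_mmHg": truth.slope_area_frac_per_mmHg,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    truth_df = pd.DataFrame(truth_rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    truth_df.to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest, truth_df


def control_spec(**overrides) -> PhantomSpec:
    """Control-genotype phantom: a compliant canal that deforms readily with IOP.

    The defaults are chosen so the analytic truth carries a height slope of
    -0.85 um/mmHg and a relative-volume slope of -0.044 per mmHg, the
    magnitude scale reported for control eyes in vivo.
    """
    base = dict(
        width0_um=200.0,
        height0_um=27.0,
        slope_height_um_per_mmHg=-0.85,
        slope_area_frac_per_mmHg=-0.044 + 0.85 / 27.0,
        noise_px=0.5,
        repeat_noise_frac=0.05,
        septa_stations=((30, 40, 0.5),),
    )
    base.update(overrides)
    return PhantomSpec(**base)


def mutant_spec(**overrides) -> PhantomSpec:
    """Stiff-outflow-phantom: smaller canal, weaker IOP response.

    Baseline volume is ~0.6x the control preset and the generating slopes are
    -0.34 um/mmHg (height) and -0.022 per mmHg (relative volume on the
    control baseline), emulating the hypo-responsive mutant eyes.
    """
    base = dict(
        width0_um=170.0,
        height0_um=19.0,
        slope_height_um_per_mmHg=-0.34,
        # relative-volume slope target: 0.598 * (slope_h/h0 + f) = -0.022/mmHg
        slope_area_frac_per_mmHg=-0.022 / 0.598 + 0.34 / 19.0,
        noise_px=0.5,
        repeat_noise_frac=0.05,
        septa_stations=((30, 40, 0.5),),
    )
    base.update(overrides)
    return PhantomSpec(**base)


def default_study_design(
    eyes_per_group: int = 6,
    repeats_per_level: int = 3,
    eye_scale_sd: float = 0.08,
    n_bscans: int | None = None,
) -> IOPExperimentDesign:
    """Two-group clamped-IOP design mirroring the in-vivo protocol.

    5 IOP offsets (-10 ... +10 mmHg), 3 repeats per level and 6 eyes per
    group, with a control and a hypo-responsive group.
    """
    overrides = {} if n_bscans is None else {"n_bscans": n_bscans}
    if n_bscans is not None:
        # keep the septated band inside range and proportionate
        lo, hi = int(0.6 * n_bscans), int(0.8 * n_bscans)
        overrides["septa_stations"] = ((lo, hi, 0.5),) if hi > lo else ()
    return IOPExperimentDesign(
        groups=(
            ("control", control_spec(**overrides)),
            ("mutant", mutant_spec(**overrides)),
        ),
        delta_iop_levels_mmHg=DEFAULT_DELTA_IOP_LEVELS,
        repeats_per_level=repeats_per_level,
        eyes_per_group=eyes_per_group,
        eye_scale_sd=eye_scale_sd,
    )
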