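"""Normalization and statistical analysis of SC morphometrics versus IOP.

Works on tidy tables of per-acquisition eye measurements (one row per
(eye, group, IOP offset, repeat)) produced by :mod:`scmorpho.pipeline`.

Two normalization schemes mirror the figures this analysis supports:

* *relative volume* -- every volume divided by the mean control-group
  volume at baseline (IOP offset 0), putting both groups on one scale;
* *per-eye normalization* -- each eye's values divided by that eye's mean
  value at the reference offset (default -10 mmHg), isolating fractional
  collapse from absolute canal size.

Inference is ordinary least squares of the (normalized) measurement on the
IOP offset, pooling all eyes and repeats of a group; the slope difference
between groups is the interaction t-test of the pooled
``value ~ offset * group`` model (ANCOVA), and per-level group contrasts
come from the two-factor cell-means model with Sidak adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "IOPResponseFit",
    "SlopeComparison",
    "normalize_relative",
    "normalize_per_eye",
    "fit_linear_response",
    "compare_slopes",
    "per_level_comparison",
    "sidak_adjust",
    "recovery_benchmark",
    "slope_difference_power",
    "plot_response",
]

_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class IOPResponseFit:
    """OLS fit of one group's measurement against the IOP offset."""

    group: str
    scheme: str
    slope: float
    intercept: float
    slope_se: float
    ci95_lo: float
    ci95_hi: float
    residual_df: int
    n_points: int


@dataclass(frozen=True)
class SlopeComparison:
    """Interaction test for a slope difference between two groups."""

    scheme: str
    slope_a: float
    slope_b: float
    delta_slope: float
    p_value: float
    test_description: str


def normalize_relative(
    measurements: pd.DataFrame,
    control_group_label: str,
    baseline_level: float = 0.0,
    value_col: str = "volume_um3",
    scheme: str = "relative_volume",
) -> pd.DataFrame:
    """Divide every measurement by the mean control value at baseline.

    Returns a copy with ``value`` (dimensionless) and ``scheme`` columns.
    """
    is_baseline = (measurements["group"] == control_group_label) & np.isclose(
        measurements["delta_iop_mmHg"], baseline_level
    )
    if not is_baseline.any():
        raise ValueError(
            f"no measurements for control group {control_group_label!r} at "
            f"baseline level {baseline_level:+g} mmHg"
        )
    denom = float(measurements.loc[is_baseline, value_col].mean())
    out = measurements.copy()
    out["value"] = out[value_col] / denom
    out["scheme"] = scheme
    return out


def normalize_per_eye(
    measurements: pd.DataFrame,
    reference_level: float = -10.0,
    value_col: str = "volume_um3",
    scheme: str | None = None,
) -> pd.DataFrame:
    """Divide each eye's values by that eye's mean value at the reference level.

    By construction each eye's normalized series averages exactly 1 at the
    reference level.  Raises, naming the eyes, if any eye lacks reference-
    level measurements.
    """
    if scheme is None:
        scheme = "normalized_height" if "height" in value_col else "normalized_volume"
    at_ref = measurements[np.isclose(measurements["delta_iop_mmHg"], reference_level)]
    ref_means = at_ref.groupby("eye_id")[value_col].mean()
    missing = sorted(set(measurements["eye_id"]) - set(ref_means.index))
    if missing:
        raise ValueError(
            f"eyes missing the reference level {reference_level:+g} mmHg: {missing}"
        )
    out = measurements.copy()
    out["value"] = out[value_col] / out["eye_id"].map(ref_means)
    out["scheme"] = scheme
    return out


def _check_fit_inputs(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 3:
        raise ValueError(f"need at least 3 points for a linear fit, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("all points lie at one IOP level; slope is unidentifiable")


def fit_linear_response(
    measurements: pd.DataFrame,
    value_col: str = "value",
    x_col: str = "delta_iop_mmHg",
    group: str = "",
    scheme: str = "",
) -> IOPResponseFit:
    """OLS of value on IOP offset, pooling all eyes and repeats of one group.

    The 95% CI uses the t distribution with ``n - 2`` residual df; on
    noiseless collinear data the residual variance, hence the CI width, is
    exactly zero.
    """
    x = np.asarray(measurements[x_col], dtype=float)
    y = np.asarray(measurements[value_col], dtype=float)
    _check_fit_inputs(x, y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    if not np.isfinite(se) or res.ssr <= _ZERO_VAR_TOL * (float(y @ y) + 1.0):
        se = 0.0  # exact interpolation: the CI collapses onto the estimate
    tcrit = stats.t.ppf(0.975, res.df_resid) if res.df_resid > 0 else math.nan
    half = tcrit * se if se > 0 else 0.0
    return IOPResponseFit(
        group=group,
        scheme=scheme or (measurements["scheme"].iloc[0] if "scheme" in measurements else ""),
        slope=slope,
        intercept=float(res.params[0]),
        slope_se=se,
        ci95_lo=slope - half,
        ci95_hi=slope + half,
        residual_df=int(res.df_resid),
        n_points=int(x.size),
    )


def compare_slopes(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    value_col: str = "value",
    x_col: str = "delta_iop_mmHg",
    scheme: str = "",
) -> SlopeComparison:
    """Test the slope difference with a pooled interaction model (ANCOVA).

    Fits ``value ~ offset + group + offset:group`` over both groups; the
    interaction coefficient equals the difference of the per-group OLS
    slopes (slope_a - slope_b) exactly, and its two-sided t-test is the
    reported p-value.  A zero-residual (noiseless) pooled model is handled
    as "no difference" (p = 1) when the interaction estimate is also zero.
    """
    xa = np.asarray(group_a[x_col], dtype=float)
    ya = np.asarray(group_a[value_col], dtype=float)
    xb = np.asarray(group_b[x_col], dtype=float)
    yb = np.asarray(group_b[value_col], dtype=float)
    _check_fit_inputs(xa, ya)
    _check_fit_inputs(xb, yb)
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    ind_a = np.concatenate([np.ones_like(xa), np.zeros_like(xb)])
    X = np.column_stack([np.ones_like(x), x, ind_a, x * ind_a])
    res = sm.OLS(y, X).fit()
    delta = float(res.params[3])
    slope_b = float(res.params[1])
    slope_a = slope_b + delta
    scale = float(np.dot(y, y)) + 1.0
    if res.ssr <= _ZERO_VAR_TOL * scale:  # noiseless data: t statistic undefined
        p = 1.0 if abs(delta) <= math.sqrt(_ZERO_VAR_TOL * scale) else 0.0
    else:
        p = float(res.pvalues[3])
    return SlopeComparison(
        scheme=scheme,
        slope_a=slope_a,
        slope_b=slope_b,
        delta_slope=delta,
        p_value=p,
        test_description="two-sided t-test on the offset x group interaction "
        "coefficient of a pooled OLS model",
    )


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment over m contrasts."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def per_level_comparison(
    measurements: pd.DataFrame,
    value_col: str = "value",
    group_col: str = "group",
    level_col: str = "delta_iop_mmHg",
) -> pd.DataFrame:
    """Group contrast at each IOP level from the two-factor cell-means model.

    The error term is the pooled within-cell variance of the group x level
    model (replicate values are the error unit); each level's group
    difference is t-tested against it and Sidak-adjusted over the number of
    levels tested.  Levels where one group has no replicates are skipped
    with a warning.
    """
    groups = sorted(measurements[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"per-level comparison needs exactly 2 groups, got {groups}")
    ga, gb = groups
    cells = measurements.groupby([group_col, level_col])[value_col]
    ss_within = float(cells.apply(lambda v: ((v - v.mean()) ** 2).sum()).sum())
    n_total = len(measurements)
    n_cells = cells.ngroups
    df_resid = n_total - n_cells
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom: need replicate values per cell")
    mse = ss_within / df_resid
    counts = cells.count()
    means = cells.mean()
    rows = []
    tested_levels = []
    for level in sorted(measurements[level_col].unique()):
        if (ga, level) not in means.index or (gb, level) not in means.index:
            warnings.warn(
                f"IOP level {level:+g} mmHg missing one group; skipped", stacklevel=2
            )
            continue
        tested_levels.append(level)
        diff = float(means[(ga, level)] - means[(gb, level)])
        se = math.sqrt(mse * (1.0 / counts[(ga, level)] + 1.0 / counts[(gb, level)]))
        if se > 0:
            t = diff / se
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
        else:
            t, p = 0.0, 1.0
        rows.append(
            {
                level_col: level,
                f"mean_{ga}": float(means[(ga, level)]),
                f"mean_{gb}": float(means[(gb, level)]),
                "difference": diff,
                "t": t,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        m = len(tested_levels)
        out["p_sidak"] = [sidak_adjust(p, m) for p in out["p_raw"]]
    return out


# ---------------------------------------------------------------------------
# Closed-loop benchmarks against the phantom generator


def recovery_benchmark(
    n_experiments: int = 200,
    seed: int = 0,
    spec=None,
    delta_iop_levels=(-10.0, -5.0, 0.0, 5.0, 10.0),
    repeats_per_level: int = 3,
    measure: str = "volume_um3",
) -> pd.DataFrame:
    """Monte-Carlo slope recovery: phantom -> full pipeline -> OLS slope.

    Each experiment images one eye at every IOP level with the given number
    of repeats, runs the complete morphometry pipeline on the rasterized
    masks, and fits the measurement-versus-offset slope.  Returns one row
    per experiment with the recovered slope, its 95% CI, the analytic truth
    and a coverage flag.

    The true slope is the linear coefficient of the analytic deformation
    model, which for the (symmetric) default levels equals the population
    OLS slope exactly.
    """
    from .phantom import IOPExperimentDesign, control_spec
    from .pipeline import measure_experiment_arrays

    if spec is None:
        spec = control_spec(n_bscans=25, septa_stations=((15, 20, 0.5),))
    s = spec.slope_height_um_per_mmHg
    f = spec.slope_area_frac_per_mmHg
    v0 = math.pi / 4.0 * spec.width0_um * spec.height0_um * spec.length_um
    if measure == "volume_um3":
        true_slope = v0 * (s / spec.height0_um + f)
    elif measure == "mean_height_um":
        true_slope = s
    else:
        raise ValueError(f"unknown measure {measure!r}")
    design = IOPExperimentDesign(
        groups=(("g", spec),),
        delta_iop_levels_mmHg=tuple(delta_iop_levels),
        repeats_per_level=repeats_per_level,
        eyes_per_group=1,
    )
    root = np.random.SeedSequence(seed)
    child_seeds = root.generate_state(n_experiments)
    rows = []
    for i in range(n_experiments):
        df = measure_experiment_arrays(design, seed=int(child_seeds[i] % (2**31 - 1)))
        fit = fit_linear_response(df, value_col=measure, group="g", scheme=measure)
        rows.append(
            {
                "experiment": i,
                "true_slope": true_slope,
                "slope": fit.slope,
                "ci95_lo": fit.ci95_lo,
                "ci95_hi": fit.ci95_hi,
                "covered": fit.ci95_lo <= true_slope <= fit.ci95_hi,
                "abs_error": abs(fit.slope - true_slope),
            }
        )
    return pd.DataFrame(rows)


def slope_difference_power(
    slope_a: float = -0.044,
    slope_b: float = -0.022,
    sd: float = 0.05,
    n_eyes: int = 6,
    delta_iop_levels=(-10.0, -5.0, 0.0, 5.0, 10.0),
    repeats_per_level: int = 3,
    n_sims: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of :func:`compare_slopes` for two linear groups.

    Simulates relative-volume measurements ``1 + slope * offset + noise``
    with Gaussian noise of the given SD for every (eye, level, repeat) and
    returns the fraction of simulations rejecting at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    levels = np.asarray(delta_iop_levels, dtype=float)
    x = np.tile(np.repeat(levels, repeats_per_level), n_eyes)
    rejections = 0
    for _ in range(n_sims):
        ya = 1.0 + slope_a * x + sd * rng.standard_normal(x.size)
        yb = 1.0 + slope_b * x + sd * rng.standard_normal(x.size)
        cmp_ = compare_slopes(
            pd.DataFrame({"delta_iop_mmHg": x, "value": ya}),
            pd.DataFrame({"delta_iop_mmHg": x, "value": yb}),
        )
        rejections += cmp_.p_value < alpha
    return rejections / n_sims


def plot_response(
    measurements: pd.DataFrame,
    fit: IOPResponseFit,
    ax=None,
    value_col: str = "value",
    x_col: str = "delta_iop_mmHg",
    color=None,
    label: str | None = None,
):
    """Scatter of measurements with the fitted line and pointwise 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(measurements[x_col], dtype=float)
    y = np.asarray(measurements[value_col], dtype=float)
    xs = np.linspace(x.min(), x.max(), 100)
    yhat = fit.intercept + fit.slope * xs
    n = x.size
    sxx = float(((x - x.mean()) ** 2).sum())
    resid = y - (fit.intercept + fit.slope * x)
    s2 = float(resid @ resid) / max(n - 2, 1)
    se_mean = np.sqrt(s2 * (1.0 / n + (xs - x.mean()) ** 2 / sxx))
    tcrit = stats.t.ppf(0.975, max(n - 2, 1))
    sc = ax.scatter(x, y, s=14, alpha=0.7, color=color, label=label or fit.group)
    c = sc.get_facecolor()[0]
    ax.plot(xs, yhat, color=c)
    ax.plot(xs, yhat - tcrit * se_mean, color=c, linestyle=":")
    ax.plot(xs, yhat + tcrit * se_mean, color=c, linestyle=":")
    ax.set_xlabel("IOP offset from baseline (mmHg)")
    ax.set_ylabel(fit.scheme or value_col)
    return ax
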