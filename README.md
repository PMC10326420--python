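# scmorpho

Morphometry of Schlemm's canal (SC) from anterior-segment OCT segmentations,
and statistical analysis of how the canal deforms when intraocular pressure
(IOP) changes.

## The problem

Schlemm's canal is the circumferential vessel at the iridocorneal angle that
drains aqueous humor out of the eye; how readily its lumen collapses as IOP
rises reflects the mechanical compliance of the adjacent trabecular meshwork,
a quantity of direct interest in glaucoma research. In vivo visible-light OCT
can image the canal cross-section by cross-section while IOP is clamped at
known offsets from baseline, but turning stacks of manually segmented B-scan
masks into comparable numbers requires a fixed measurement convention.
`scmorpho` implements that convention as a tested, reusable pipeline, for
researchers who have per-B-scan binary lumen masks and want per-eye
morphometrics and IOP-response slopes.

## The measurement model

For each B-scan, 8-connected lumen components are extracted and the SC parts
are selected: the anchor is the largest connected lumen (optionally restricted
to a region of interest marking the iridocorneal-angle neighbourhood), and
every part with area ≥ 20% of the anchor's is kept. Each part gets the
**equal-second-moment ellipse** — the ellipse whose normalized central second
moments match the component's, computed in physical μm coordinates with the
per-axis +(pixel size)²/12 correction:

    u_xx = μ20/n + s_lat²/12,  u_yy = μ02/n + s_ax²/12,  u_xy = μ11/n
    major = 2√2 · √(u_xx + u_yy + c),  minor = 2√2 · √(u_xx + u_yy − c),
    c = √((u_xx − u_yy)² + 4 u_xy²)

Per cross-section: *width* = Σ major axes, *height* = area-weighted mean of
minor axes, *area* = Σ component areas. Per eye, over a 1.5 mm analyzed
length: *volume* = Σ area × B-scan spacing. Measurements at 5 IOP offsets
(−10 … +10 mmHg, 3 repeats each) are normalized (to the control-group
baseline mean, or per-eye to the −10 mmHg reference) and fitted by OLS,
value ~ ΔIOP; the group slope difference is the interaction t-test of the
pooled ANCOVA model, and per-level group contrasts use the two-factor
cell-means model with Šídák adjustment.

Because such studies rarely deposit raw image volumes, the package ships a
phantom generator (`scmorpho.phantom`) producing mask stacks of elliptical
lumens with a linear IOP-deformation model and *exact analytic ground truth*,
so the whole pipeline is validated by closed-loop parameter recovery.

## Worked example

```python
from scmorpho import phantom, pipeline, iopfit

design = phantom.default_study_design()          # 2 groups x 6 eyes x 5 IOP levels x 3 repeats
df = pipeline.measure_experiment_arrays(design, seed=7)

rel = iopfit.normalize_relative(df, "control")   # volume / control baseline mean
for g in ("control", "mutant"):
    fit = iopfit.fit_linear_response(rel[rel.group == g], group=g, scheme="relative_volume")
    print(g, round(fit.slope, 4), (round(fit.ci95_lo, 4), round(fit.ci95_hi, 4)))
cmp_ = iopfit.compare_slopes(rel[rel.group == "control"], rel[rel.group == "mutant"])
print("slope difference p =", cmp_.p_value)
```

prints

```
control -0.0447 (-0.047, -0.0424)
mutant -0.0221 (-0.0246, -0.0196)
slope difference p = 1.0840074259629896e-27
```

i.e. the control phantom loses ~4.5% of its baseline canal volume per mmHg of
IOP elevation, the stiff "mutant" phantom only ~2.2%, and pooled ANCOVA calls
the slopes different — recovering the generating parameters (−0.044 and
−0.022 per mmHg) through the full raster → components → ellipse → volume →
regression chain.

The same analysis runs from the shell on on-disk stacks:

```
scmorpho phantom generate --out exp/ --seed 7
scmorpho morpho run --manifest exp/manifest.csv --out results/
scmorpho iopfit run --measurements results/eye_measurements.csv --out results/
scmorpho iopfit recover --phantom-dir exp/
```

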