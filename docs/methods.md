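# Methods

## Palaeothermometry

Calcification temperature is obtained by inverting an exponential Mg/Ca
calibration, Mg/Ca = a·exp(b·T), with species-specific central-Atlantic
defaults a = 0.6 ± 0.16 mmol mol⁻¹ and b = 0.075 ± 0.006 °C⁻¹. Alternative
published equations can be supplied as `CalibrationEquation` parameters or
through the YAML config.

Where a site has duplicate dissolutions, the **first-listed ratio** is
converted to temperature by default and the replicate informs only the
uncertainty budget. This primary-value rule is the only one consistent with
the reference temperature column shipped with the package (e.g. the site
with ratios 2.92 and 2.80 is listed at 21.1 °C = ln(2.92/0.6)/0.075, not at
the replicate-mean temperature); averaging is available behind
`mode="mean"`.

Temperature uncertainty is first-order propagation. The analytical term is
σ_T = σ_Mg/Ca / (b·Mg/Ca); with σ_Mg/Ca = 0.14 mmol mol⁻¹ this gives
0.5–0.6 °C over the observed ratio range. Calibration-parameter terms
(σ_a/(b·a) and |ln(Mg/Ca/a)|·σ_b/b, combined in quadrature under an
independence assumption) are **off by default**: the reference temperature
column is reproducible without them, and the published "average error"
figure of ~0.8 °C is not derivable from the stated analytical uncertainty
alone, so it is treated as descriptive and never asserted. A Monte-Carlo
cross-check in the test suite confirms the first-order analytical term
within 5%.

Ratios implying temperatures below −2 °C are flagged implausible rather
than rejected. Contaminant ratios (Al/Ca, Fe/Ca, Mn/Ca) are carried and
reported but never gate a sample.

## Seawater state (EOS-80)

σθ is the potential density anomaly at reference pressure 0 dbar from the
one-atmosphere International Equation of State of Seawater (UNESCO 1983
polynomial), on the practical salinity scale. EOS-80 was chosen over
TEOS-10 because the at-depth density columns this package consumes and
reproduces are practical-salinity based; the function is isolated behind
`hydrography.sigma_theta` so a TEOS-10 backend could be swapped in. The
implementation reproduces the UNESCO check values (ρ(35, 5, 0) =
1027.67547, ρ(0, 5, 0) = 999.96675, ρ(35, 25, 0) = 1023.34306 kg m⁻³) to
5 decimals. For the upper 300 m the difference between in-situ and
potential temperature (<0.03 °C) is ignored.

## Profiles and seasonal averaging

Profiles live on the standard climatology grid — 2.5 m, then every 10 m to
200 m and every 20 m to 300 m — though any strictly increasing grid with ≥2
nodes is accepted. Interpolation is piecewise linear, exact at nodes, with
extrapolation refused.

Sites poleward of ±23° latitude use the node-wise mean of the **three
consecutive warmest months**, ranked by shallowest-node temperature with
wrap-around across the year boundary; equatorward sites use the annual
mean. The consecutive-triple rule reproduces the canonical August–October
(northern) and February–April (southern) warm seasons while remaining
well-defined for any seasonal cycle. The months used are recorded on the
output profile.

The salinity maximum of a profile is the global node maximum (under
piecewise-linear interpolation no interior maximum can fall between nodes).
Ties resolve to the shallowest node and are flagged; a maximum at the
shallowest node is reported with `is_subsurface=False` — the subtropical
gyre case, where salinity declines monotonically from the surface.

## ACD inversion

The apparent calcification depth is the **shallowest** depth where the
piecewise-linear temperature profile equals the shell temperature. The
shallowest-crossing rule reflects a mixed-layer dwelling species: deeper
crossings on non-monotone profiles are artefacts of temperature inversions
and are surfaced via a `multiple_crossings` flag instead of being resolved
by any hidden rule. Targets warmer than the shallowest node clamp there
(`surface_clamped`, at 2.5 m rather than 0 m — the profile domain); targets
colder than the whole profile return `no_crossing` with no depth. There is
no extrapolation below 300 m.

The 1σ depth interval inverts t ± σ deterministically (warmer bound →
shallower depth), clamping to the profile range with a `bound_truncated`
flag; a Monte-Carlo resampling interval exists purely as a cross-check and
agrees on linear profiles. Against a 0.01 m brute-force scan, the inversion
recovers programmed depths on randomised monotone profiles to better than
0.1 m.

Salinity at the ACD is interpolated linearly; σθ at the ACD is evaluated
from the interpolated (S, T) pair. The band width max−min of σθ-at-ACD
across a transect is exposed as `isopycnal_band`.

## Shell traits

All site-level traits are computed **from sample means** (mean weight /
mean area, etc.), never as means of per-specimen ratios — the convention
required for a table of averaged measurements to reproduce site-level trait
values exactly. Canonical units are μm²/μm³/μg; bulk shell density
weight/potential-volume lands in g cm⁻³ because μg nl⁻¹ ≡ g cm⁻³.

Mean wall thickness is calcite volume over the **total** (inner + outer)
segmented surface; in the thin-wall limit V/SA → wall/2. If only the outer
surface is available the trait is left absent rather than approximated,
since substituting the outer surface alone roughly doubles the value.
Biovolume is stored as an independent measurement and never recomputed as
potential − test: in the reference data the two disagree (site 1: 20.807 nl
potential vs 9.705 + 9.988 nl), the residual presumably being aperture and
foramen space sealed by the enclosed-volume construction.

The organic-tissue density estimate, mean BSD − 1.025 g cm⁻³ seawater, is a
descriptive difference, not a buoyancy model.

## Tomogram metrics

Inputs are already-labelled voxel volumes ({background, test, lumen,
debris, standard}, isotropic spacing, default 1.2 μm); no reconstruction or
grey-level segmentation is performed. Volumes are voxel counts × voxel³.

Surface areas come from a marching-cubes iso-surface at level 0.5 of the
label mask after Gaussian smoothing with σ = 1 voxel. Smoothing matters: on
a digitised sphere the raw binary iso-surface carries a ~9% staircase
overestimate (and voxel-face counting ~50%, kept only as a cross-check),
while the smoothed estimator is accurate to ≲0.5%. The smoothing erodes
features thinner than ~3 voxels, hence the phantom generator requires ≥5
voxels across a wall. Hollow objects report inner + outer surface together,
which is what the V/SA thickness needs.

The "potential specimen volume" (shell + enclosed interior, as if chambers
were filled with protoplasm) is approximated by morphological closing of
the test mask with a ball of configurable radius (default 15 μm, larger
than typical aperture half-widths) followed by hole filling. The closing is
computed with exact Euclidean distance transforms (dilate = EDT ≤ r, then
the matching erosion), which is equivalent to a ball-kernel closing and
fast at large radii. `sealed=False` signals that hole filling captured no
interior cavity — an aperture wider than the ball, or a solid object — in
which case the volume underestimates the true enclosed volume. The
approximation is validated on phantoms (closed-aperture volume within 2% of
4/3·πR³); it is not asserted to equal any interactive ambient-occlusion
result.

CT numbers are standardised by the linear map sending the background mean
grey value to 0 and the co-scanned calcite-standard mean to 1000 (an
arbitrary reference on a relative scale); the construction is invariant
under affine rescaling of the raw intensities, so only relative
comparisons between specimens are meaningful. Dissolution-grade thresholds
are not reproduced; the standardised mean is reported raw.

## Regression matrix

Each cell is closed-form OLS; r² equals squared Pearson correlation
(asserted to 1e−12 against an independent oracle), p-values from the
classical slope t-test on n−2 df, no multiple-testing correction.
Pairwise-complete filtering is logged, never silent; site exclusions apply
to every cell and are recorded on the matrix. Annotations (best r² per
trait column, negative-slope anti-correlations) are derived from the cells,
not stored.

Regressions on the packaged tables run on printed-precision inputs; the
reproduction tolerance of ±0.02–0.03 on r² absorbs the use of unrounded
values upstream of printing. The omit-two-sites reruns published for the
dissolution-affected equatorial pair are computed but not asserted: they
are not reproducible from the rounded at-depth density column (recomputation
gives materially lower r²), the unrounded environmental values being
available only in supplementary material.

## Synthetic data

The profile generator uses a logistic thermocline — T(z) = T_deep +
(SST_month − T_deep)·f(z), f a logistic in depth normalised to 1 at 2.5 m —
with sinusoidal monthly SST modulation, and a Gaussian salinity bump whose
depth, amplitude and width are free; gyre presets put the bump at the
surface to exercise the no-subsurface-maximum branch. Two parameters
(mixed-layer depth, decay scale) are the only shape controls: realism
beyond "mixed layer over thermocline" is deliberately not attempted, since
what is under test is the inversion's behaviour, not ocean physics.

Shell populations: mean weight linear in the salinity driver (default
slope 2.2 μg per salinity unit around a 28 μg baseline at salinity 36,
specimen noise 2.5 μg), areas and volumes log-normal with relative SDs
matching the observed intra-sample variability (9–16%), test volume drawn
as a fraction of each specimen's potential volume so consistency is
enforced by construction. The 16-site synthetic transect spans 31° N to
25° S, interpolating the regime parameters in |latitude|, fixes a true
calcification depth per site, reads the matching temperature off the
seasonally appropriate profile and pushes it through the forward
calibration — so the pipeline's recovered depths, salinities and
weight–salinity slope can be compared against programmed truth. All
generators are bit-reproducible under their seeds.

What the synthetic data do **not** emulate: real climatological
variability, profile noise structure, carbonate-system fields, dissolution
effects on Mg/Ca, or any covariance between traits beyond the programmed
salinity response. Passing recovery tests therefore demonstrates
correctness of the machinery, not fidelity of any geophysical claim.

## Problem sizes and determinism

Phantoms in the validation suite use spheres of 40–50 μm radius at 0.75–2 μm
voxels (grids ≲150³), where discretisation errors are comfortably inside the
stated 2–3% tolerances and the whole suite runs in seconds. Monte-Carlo
cross-checks use 10⁵ draws (uncertainty) and 500 replicates (slope
recovery). Every stochastic test fixes its seed; pipeline outputs are pure
functions of config + inputs + seed, and reruns are byte-identical.

## Known limitations

- Per-site ACDs for the reference transect are not recomputed (the
  underlying climatological profiles are not bundled); at-depth salinity
  and σθ columns are consumed as given, and the inversion itself is
  validated on synthetic profiles instead.
- EOS-80, not TEOS-10; adequate for density anomalies in the upper 300 m at
  the precision used here.
- The closing-based potential volume depends on the radius parameter when
  apertures are wide or walls are rough; `sealed` must be checked.
- Mean wall thickness cannot be derived from the bundled tables (total
  segmented surfaces are not tabulated) and is reported only when a total
  surface is supplied.
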