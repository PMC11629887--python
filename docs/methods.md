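# Methods

## The follicle model

The basement membrane (BM) is a 1-D material curve laid out as a "U": two
parallel stalks of length 40 µm joined by a semicircular bulb of radius
15 µm (total arc ≈ 127 µm), discretized at ≤ 0.5 µm.  The model is the
2-D mid-plane of the follicle; live measurements around the circumference
show a consistent shape and expansion rate, which justifies dropping the
third dimension (an optional 3-identical-z-plane mode exists for the
three-plane averaging used at measurement time).  Regions are fixed
analytically rather than hand-annotated: the tip is the semicircle between
the two bend points, each stalk is split at the midpoint of its
non-junction part into lower (tip-adjacent) and upper halves, and a 5-µm
junction band sits at each open end.  Region boundaries are half-open with
ties going to the more tip-ward region.

Each material point carries a labeled fraction *g* ∈ [0, 1] (the
eGFP-collagen-IV proxy), a photoconverted fraction *r* (mKikGR red pool,
*g* + *r* ≤ 1), and a Gaussian cross-section sigma *w* (µm).

### Turnover

First-order replacement with unit steady state — the simplest law
consistent with full recovery at the tip and with pulse-chase replacement
of photoconverted protein:

    dg/dt = k(s) (1 − g − r),    dr/dt = −k(s) r.

Removed red protein transits through the unlabeled pool before green
incorporation, so with *b* = 1 − *g* − *r*:

    r(t) = r₀ e^{−kt},    b(t) = (b₀ + k r₀ t) e^{−kt},    g = 1 − b − r,

which reduces to g(t) = 1 − (1 − g₀)e^{−kt} after a pure bleach.  The
integrator applies this exact one-step solution per dt ≤ 1 min step, so
multi-step trajectories agree with the closed form to machine precision
(tested at 1e-6).

### Expansion

Each inter-point segment elongates at a fractional strain rate ε(s) per
minute, applied as the exact per-step factor e^{ε dt} (forward-Euler
1 + ε dt would miss the e^{εT} oracle by ~1e-4 over 7 h).  Rates are
back-computed from endpoint percentages as ln(1 + Δ)/T because only
endpoint changes are reported: tip ln(1.30)/420 min⁻¹, lower stalk
ln(1.22)/570 min⁻¹, upper stalk 0 in the control preset (the reported ~−3 %
is within measurement noise; negative rates are supported).

### Profiles are material fields

Turnover and strain profiles are per-region plateaus joined by linear
transition ramps (default half-width 1 µm) — continuous, as required, while
honoring the per-region endpoint rates.  Pure midpoint-anchored linear
interpolation would dilute the tip plateau by ~25 % and could not reproduce
the printed endpoint percentages; the true spatial profile shape between
region anchors is unknown, and ramped plateaus are the package's modeling
choice.  Profiles are anchored to the *initial* region boundaries and
advect with the tissue: bleached or tracked material keeps its local rates
as it grows.  A geometry-anchored alternative would let tip material
"leak" out of the fixed-length semicircular arc and stop growing, breaking
the stated +30 % compartment ground truth; the material anchoring makes a
constant-strain compartment exactly exponential.  The geometric layout
itself keeps the bulb radius fixed (growth lengthens the stalks, i.e. the
tip invades downward); under the MMP-inhibition preset an optional radial
growth rate widens the bulb as a stated geometric proxy for
perpendicular-division cell influx — there is no mechanics (no force
balance, stiffness, or tension) anywhere in the model.

### Cells and divisions

Basal cells are arc-anchored and advect with their material neighborhood
plus an optional slip velocity (slip = 0 reproduces fully BM-coupled
motion).  Divisions are drawn per region at a configurable rate
(events/cell/h) with daughter separation 6 µm and an allocation-angle
mixture over horizontal [0°, 30°), oblique [30°, 60°], perpendicular
(60°, 90°]; S-phase entry (for EdU-style labeling windows) is a separate
per-region rate.  All stochastic draws flow from a single seeded generator
owned by the state, iterated in stable cell order, so trajectories are
bit-reproducible.

## Synthetic imaging

Frames render the curve with a Gaussian cross-section whose sigma is the
local *w* and whose **peak** (not integral) is proportional to the local
labeled fraction, so thickness changes cannot masquerade as label changes —
matching the use of line intensity as a label proxy.  The curve is
densified to 0.1 µm before the nearest-point distance lookup so raster
error stays below ~1 %.  Noise is shot noise (Poisson at photon_scale 100,
giving centerline SNR ≈ 10, typical of confocal explant imaging) plus
Gaussian read noise (σ 0.01); both off when zero.  Defaults: 0.5 µm/px,
192×192 px, frames every 10 min (FRAP) or 30 min (expansion), background
0.1.  Simulated experiments emit the image series (TIFF + JSON sidecar),
an event log, and a per-frame ground-truth manifest that tracks each
bleach event's advected material interval.

What the generator does **not** emulate: point-spread-function optics
beyond the Gaussian cross-section, photobleaching during imaging, drift or
registration artifacts, 3-D tube geometry, and cell-image realism (cell
quantification consumes track tables, as in the original manual tracking).
A green test therefore establishes correctness of the measurement chain on
an idealized but noisy microscope, not robustness to those artifacts.

## Quantification pipeline

**FRAP.**  The centerline is traced (threshold–skeletonize–walk; in test
mode the ground-truth polyline is used directly), intensity is sampled as
per-station maxima across a ±2-px perpendicular band (smoothed 1 µm along
the arc first so the max does not ride the noise at low signal), averaged
along the bleached interval and across z planes, background-subtracted
(median of pixels > 3 px from the trace) and divided by the mean over all
pre-bleach frames (the simulator provides 3).  The recovery is fitted by
ordinary least squares on time — the linear fit is deliberate, because
recovery has no plateau on the imaging timescale; an exponential fit is
available as a cross-check but is never the reported value.  t50 comes
from inverting the line, flagged when extrapolated or undefined.  The
band-max readout has a known +1–2 percentage-point bias at near-zero
signal (max of noisy samples); it is inherent to the ridge-max protocol
and well inside the ±5-point acceptance band.

**Bleached-edge fiducials.**  Edges are half-height crossings between the
local bright and dark plateaus of the centerline profile, sub-sampled by
linear interpolation.  Two corrections matter at the protocol's 2–3-µm
stripe widths: (1) after Gaussian smoothing a stripe only a few σ wide
never reaches its dark plateau, so the observed depth is de-attenuated by
the two-edge erf factor before the 50 % level is set; (2) spatial turnover
gradients tilt the recovering dark floor, so the floor is sampled just
inside each crossing and extrapolated linearly to the crossing.  The
tracking path samples the profile as a band **mean** (a constant
cross-section factor that leaves crossings unbiased) with light 0.25-µm
pre-smoothing and σ = 0.5 µm detection smoothing — the bias of these
estimators scales with σ², and the defaults keep null-expansion false
change below 1 %.  detect_bleach_edges retains a 1-µm default for
standalone use.  Edges are matched frame-to-frame by nearest arc position
within 6 µm with matching polarity (ties raise an error listing the
candidates); re-bleach rounds re-target the advected material of the
original stripes, one event-log record per compartment, so identity is
carried by interval overlap.  Compartment length changes are
100·(L(t₁) − L(t₀))/L(t₀) on the frames nearest the requested times.

**Thickness.**  Supra-threshold area over window length on a 5–10-µm
window, implemented as interpolated-crossing widths at 0.25-µm stations —
the threshold is 50 % of the *local* per-station peak so label-fraction
gradients and gain changes do not bias the width.  For a Gaussian section
this converges to the FWHM 2σ√(2 ln 2).

**Displacement decomposition.**  With normalized (percent) changes of the
cell and BM distances from a reference bleached edge, the BM contribution
is 100·(BM %)/(cell %) and the residual is their difference in percentage
points; zero cell displacement yields an undefined flag, not an exception.
The ratio is computed per record; any averaging across records happens at
the reporting layer, so both per-record and pooled readouts are available.

**Division angles.**  θ is the acute angle between the daughter–daughter
axis and the BM tangent (central difference over ±2 µm of arc — larger
than pixel noise, smaller than the tip curvature radius), folded into
[0°, 90°].  The 30° and 60° boundaries belong to the oblique class because
horizontal and perpendicular are defined by strict inequalities.  Reported
proportions are rounded to one decimal; only the horizontal and
perpendicular percentages are primary readouts (the oblique remainder is
derived by subtraction).

**Shape factor.**  The follicle axis is the principal axis of the outline
(reproducible, unlike manual annotation); L_HF runs from the junction
chord — fixed to the junction-band boundary, since its manual placement is
unspecified — to the apex, W_HF is the maximal perpendicular extent in the
lower half, S = L_HF/W_HF.  From images the outline is the largest
connected supra-threshold component after morphological closing.

**Statistics.**  Genotype percentages round to one decimal and are tested
by Pearson chi-square against 1:2:1; group comparisons are two-tailed
unpaired t tests, one-way ANOVA with Tukey post-hoc, or two-way ANOVA with
Tukey on the cell means, with significance stars at 0.05/0.01/0.001/0.0001.
Normality is assumed and not gatekept, mirroring the source analyses.
Reports are assembled deterministically (sorted keys, content hashes) so
identical runs are byte-identical.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| k (tip/lower/upper/junction) | 3.38e-3 / 1.24e-3 / 8e-4 / 3.46e-4 | min⁻¹ | measured endpoints; upper stalk is not printed and is interpolated between its neighbors |
| ε (tip/lower) | 6.25e-4 / 3.49e-4 | min⁻¹ | ln(1+Δ)/T from +30 % (7 h) and +22 % (9.5 h) |
| thickness σ (tip vs junction/upper) | 1.0 vs 1.55 | µm | junction/upper measured 55 % and 53 % thicker than tip/lower |
| bleach ROI | 15 µm long, 3 µm stripes | µm | the photobleaching protocol (15 ± 2 µm × 2–3 µm) |
| re-bleach period | 150 | min | within the protocol's 2–3 h; two rounds fit a 7-h session |
| pixel size / frame interval | 0.5 / 10–30 | µm/px, min | acquisition settings; FRAP at ~10 min, tracking at 30 min |
| photon_scale / read σ | 100 / 0.01 | – | centerline SNR ≈ 10 |
| dt | 1 | min | stability bound; exact per-step updates make accuracy seed-independent |

## Known limitations

* The 1-D material model has no mechanics; MMP-inhibition widening is a
  geometric proxy, so shape-factor trajectories are qualitative
  (directional), not quantitative predictions.
* Edge tracking assumes the protocol's stripe widths (≈2–4 µm after
  growth); much wider or narrower stripes change the bias corrections'
  accuracy.
* The FRAP band-max readout is biased ~+1–2 points at near-zero signal
  (see above); use noise-free mode for unbiased methodological checks.
* Blind-mode centerline tracing handles the clean synthetic ridge; it is
  not a general curvilinear tracker for cluttered real images.
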