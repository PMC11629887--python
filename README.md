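# bmdyn

Quantification of basement-membrane (BM) dynamics in growing hair
follicles from time-lapse fluorescence imaging — together with a
ground-truthed synthetic follicle/microscope simulator so every stage of
the analysis can be validated without microscope data.

During early hair-follicle morphogenesis the BM (read out via fluorescently
tagged collagen IV) is not a static substrate: its protein turns over with
a spatial gradient (fast at the invading tip, slow at the epidermal
junction), it expands directionally (~+30 % at the tip over 7 h), and
epithelial basal progenitors largely *ride* this expanding matrix rather
than crawling over it.  Broad-spectrum MMP inhibition suppresses both
turnover and expansion, shifts division angles perpendicular, and widens
the follicle.  `bmdyn` implements the measurements behind those statements
for researchers doing live BM imaging or modeling matrix-driven
morphogenesis.

## The model and the measurements

The simulator treats the BM as a 1-D material curve (a "U": two stalks plus
a semicircular bulb) with arc coordinate *s*, labeled fraction *g*
(eGFP-collagen proxy), photoconverted fraction *r* (mKikGR pulse-chase),
and cross-section width *w*:

* **Turnover** — first-order replacement with unit steady state,
  d*g*/d*t* = *k*(*s*) (1 − *g* − *r*), d*r*/d*t* = −*k*(*s*) *r*.
  FRAP recovery therefore follows 1 − e^(−*kt*); the tip control rate is
  *k* = ln 2 / 205 min⁻¹.
* **Expansion** — each material segment elongates at strain rate ε(*s*)
  per minute (length(*T*) = length(0) · e^(εT)); regional rates are
  back-computed from endpoint percentages as ln(1 + Δ)/T.
* **Quantification** — FRAP curves are normalized to the pre-bleach mean
  and fitted by simple linear regression; BM compartments are delimited by
  photobleached stripes whose edges (half-height crossings of the
  centerline intensity profile, sub-pixel) act as material fiducials,
  maintained by re-photobleaching every 2–3 h; thickness is
  supra-threshold area / window length; division angles are classified by
  the acute angle θ to the local BM tangent (horizontal < 30°,
  perpendicular > 60°); the shape factor is S = L_HF / W_HF.

## Worked example

```bash
python examples/frap_recovery.py
```

```
turnover rate k        : 0.003381 /min (half-life 205 min)
recovery at 205 min    : 50.2 %  (expected ~50% -- half the bleached collagen replaced)
linear-fit slope       : 0.226 %/min
fitted t50             : 197 min
exponential cross-check: k = 0.003333 /min (should recover the simulated rate)
```

A BM with tip-rate turnover is bleached, imaged every 10 min at realistic
noise, and the pipeline-extracted recovery curve crosses 50 % at the
configured 205-min half-life; the exponential cross-check recovers the
simulated rate to ~1 %.  `examples/bm_expansion.py` does the same for
compartment tracking (control tip ≈ +30 %, MMP-inhibited ≈ +6 %, static
stalks within the ~1 % measurement floor), and the other scripts cover
division angles, thickness/shape, displacement decomposition, and the
group statistics.

## Scenario presets

`control` and `mmpi` YAML presets (under `src/bmdyn/presets/`) hold the
regional turnover/strain/thickness/division parameters of the normal and
MMP-inhibited follicle; `bmdyn.frap_scenario(...)` and
`bmdyn.expansion_scenario(...)` build complete imaging protocols from
them, and `bmdyn.simulate_experiment(...)` returns the rendered TIFF-ready
series, the bleach/conversion event log, and a per-frame ground-truth
manifest.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline endpoint quantities from scratch by running the
full simulate → render → quantify pipeline: the five FRAP recovery
endpoints (tip/lower-stalk/junction/measured-tip/MMP-inhibited rates read
off the normalized curve at 205 or 210 min, averaged over five seeds), the
two 7-h tip-expansion percentages from fiducial tracking, the
displacement-decomposition worked example, and the junction-over-tip
thickness excess from a noise-free render.  Output is JSON keyed by target
id with the value and the number of replicates used.
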