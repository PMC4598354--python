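# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `foamplug`, and what the synthetic data do and do not establish
about real recordings.

## The measurement

A foam plug in an inclined tube phantom, filmed side-on, traces a
plug-length trajectory L(t): zero before injection, an approximately
linear rise while the injected foam volumetrically expands into a coherent
plug, and an approximately linear recession as the foam degrades and the
blood substitute reclaims the lumen. Both phases are therefore summarised
by straight-line fits:

- formation rate = |OLS slope| of L vs t over the expansion phase (mm/s);
- degradation rate DR = |OLS slope| over the degradation phase (mm/s);
- dwell time DT = 10 / DR (s/cm). DR is in mm/s and DT in s/cm, so the
  inverse carries a factor of 10 mm/cm; this bridge reproduces the
  conventional pairing (e.g. DR ≈ 3.42 mm/s ↔ DT ≈ 2.92 s/cm).

Rates are reported as magnitudes: once the phases are split, the sign of
a slope carries no information. r² of each fit is kept as a diagnostic —
on well-formed plugs with sub-mm tracking noise it should exceed 0.95.

### Unit conversions

A linear front speed v (mm/s) in a tube of inner diameter d (mm)
corresponds to the volumetric rate Q = v·π(d/2)²/1000 mL/s, and a V mL
injection at Q lasts V/Q seconds. Full precision is kept internally;
display rounding (2 dp for rates, 1 dp / nearest second for durations)
matches the precision conventionally printed.

## Phase splitting

1. Smooth L(t) with a moving median (default window 5 frames). The median
   is robust to single-frame tracker dropouts. The effective window is
   capped at the largest odd integer ≤ n/2 so short series are not
   over-smoothed.
2. If the smoothed maximum is below the plug gate (default 5 mm), raise
   `NoPlugFormed`: the foam never built a measurable plug. The gate is
   caller-configurable; for very long rendered tubes 10 % of the tube
   length is a reasonable alternative.
3. The peak is the argmax of the smoothed series (earliest index on
   ties), refined to the raw argmax within half a smoothing window — the
   median filter can displace a sharp peak by a couple of frames.
4. Phase endpoints are where the smoothed series crosses 5 % of its peak.
   This keeps two noise floors out of the fits: the pre-injection
   baseline, where Gaussian tracking noise clipped at zero produces many
   spurious small positive lengths, and the post-degradation tail. Within
   the retained ranges all samples lie on the respective line, so the
   cut-off does not bias the slopes.
5. The single sample at the peak sits on the kink between the two lines
   and belongs to neither; it is excluded from each fit whenever at least
   three samples remain. Exact piecewise-linear input is then recovered
   exactly (to floating-point precision), which the tests exploit.
6. A series that ends before any decline raises
   `IncompleteDegradation` — a truncated recording, distinct from a
   failed plug.

## Plug tracking

The tracker assumes a side-on view of a single straight tube and reduces
each frame to a 1-D problem:

1. **Axial profile** — mean intensity across the transverse band (ROI)
   at each axial pixel.
2. **Background subtraction** — against a foam-free reference profile
   (the first frame by default). If no background is supplied and the
   first frame shows a plug-sized bright band, a `CalibrationError` is
   raised rather than silently mis-measuring.
3. **Binarisation** — Otsu's threshold on the difference profile,
   floored at 6× a high-frequency noise estimate (1.4826·median|Δ|/√2 of
   the profile's first differences). The floor makes a foam-free frame
   segment to nothing (Otsu alone would split pure noise) while scaling
   with any global intensity rescaling, so segmentation is invariant to
   exposure changes.
4. **Run selection** — the plug is the longest above-threshold run of at
   least the minimum plug length (default 5 mm), ties broken toward the
   injection end. A run anchored near the injection end also qualifies
   when its leading edge passes the gate even if its own extent falls
   short: the trailing edge is x = 0 by definition, and a small foam
   sliver present in the background frame cancels the first pixels of
   the difference profile.
5. **Length** — L = leading-edge pixel × mm/px, measured from the
   injection end (frames are flipped internally when the injection port
   is on the right). Frames with no plug give L = 0, never NaN, so phase
   detection always sees a complete series. Monotonicity is never
   enforced; noise is legitimate data. An optional 3-frame running median
   is available but off by default.

The instrument that inspired this stage is not publicly documented; the
profile/Otsu/longest-run design is this package's own, chosen to be
deterministic and fully testable against rendered ground truth.

## Synthetic data

The generator produces exactly the structures the analysis consumes, with
known ground truth:

- **Trajectories** — piecewise linear (no curvature is simulated because
  none is modelled downstream), with i.i.d. Gaussian noise on length
  (default σ = 0.5 mm, a tracking-jitter-scale choice; clipped at zero).
  `plug_fails=True` caps the peak at 2 mm — below the 5 mm gate — to
  model foams that cannot displace the blood substitute, as happens for
  every formulation in a wide tube at steep inclination.
- **Videos** — the tube as a horizontal band; foam bright (0.9) over a
  darker blood substitute (0.2), with a seeded static bubble texture and
  per-frame Gaussian sensor noise (default σ = 0.02). The frame interval
  defaults to the camera's 30 ms. The blood substitute's viscosity
  (0.003 Pa·s) and density (1078 kg/m³) are carried as metadata only.
- **Bubble fields** — lognormal diameter populations. The d³-weighted
  version of Lognormal(µ, σ²) is Lognormal(µ+3σ², σ²), so the analytic
  volume-weighted median exp(µ+3σ²) serves as an independent oracle.
  Frames show non-overlapping dark discs on a bright background, placed
  largest-first by seeded rejection sampling.

All randomness flows through explicit integer seeds; there is no global
random state, and identical seeds give bit-identical output.

What passing the round trips shows — and does not. The synthetic videos
share the real recordings' geometry, contrast polarity, noise scale and
frame rate, but not their artefacts: no illumination gradients, lens
distortion, meniscus effects, partial-volume blur at the foam front, or
bubble streaming ahead of the plug. Recovery to sub-pixel accuracy on
rendered data validates the algorithmic chain, not robustness to those
artefacts; real deployments should check the r² diagnostics and the
tracked series visually.

## Bubble sizing

Dark objects on a bright background are Otsu-thresholded, holes filled,
connected components labelled. Components are discarded when smaller than
the minimum diameter (default 2 px equivalent), touching the frame border
(truncated diameters), or with circularity 4πA/P² < 0.6 (overlapping
clumps). Equivalent diameter = 2√(area/π) × scale. Frames whose two Otsu
classes differ by less than 0.1 intensity units are treated as empty —
otherwise a blank frame's sensor noise would be split into speckle.
Circularity is capped at 1 (pixelated small discs can nominally exceed it).

"Volume fraction" is interpreted as the q3 convention: each bubble weighs
d³ (spherical volume). The instrument class that motivated this stage
does not document its weighting or binning; d³ with 50 µm bins over
0–1550 µm is this package's documented assumption, and the bin grid
auto-extends in 50 µm steps when a sample exceeds it so fractions always
sum to 1. Replicates are pooled by total volume (physical pooling of
acquisition intervals), so replicates with more bubbles weigh more;
pooling requires identical bin grids. The volume-weighted median is
computed exactly from the retained diameters when available, otherwise by
interpolation within bins.

## Condition aggregation

A condition = tube diameter × inclination × method × gas × LGR × delay,
with N = 4 replicates by default. Config validation enforces that the
canister microfoam (PEM) keeps its fixed formulation (LGR 1:7, 35:65
CO₂:O₂). Per condition:

- mean DT over successful replicates;
- percentage deviation of the mean = mean absolute deviation / mean ×
  100. This is the most direct reading of the phrase; the coefficient of
  variation (SD/mean) is available via `method="cv"`. Without raw
  replicate data the two cannot be adjudicated externally, so the choice
  is documented rather than claimed.
- replicates raising `NoPlugFormed` are counted (`n_failed`) and excluded
  from the mean, never imputed as DT = 0; with fewer than two successes
  the deviation is reported as NaN. A condition with zero successes
  raises `AllPlugsFailed`.
- It is likewise undocumented whether such deviations are conventionally
  computed over the N replicate DTs or over pooled raw measurements; this
  package uses the N replicate DTs.

`run_study` executes a YAML-declared study (simulation parameters or
series files per condition), derives one noise seed per replicate from
the study seed via `SeedSequence([seed, condition, replicate])` (kept
below 2³¹), and writes per-replicate JSON, per-condition CSVs, the
comparison table and a run log containing the config SHA-256 and all
seeds. Outputs contain no timestamps and use fixed float formatting, so
identical config + seed reruns are byte-identical.

## Problem sizes and defaults used in validation

- Parameter recovery: 100 simulated injections, DR uniform in
  [0.3, 5] mm/s, formation rate in [20.9, 52.1] mm/s (the observed range
  of plug formation rates), peak 100 mm, σ = 0.5 mm, 30 ms sampling.
- Rendered round trips: 20 videos of 200 frames at 800×100 px,
  0.25 mm/px, intensity noise 0.05. Tracking error is evaluated where
  the plug is detectable — L = 0 or L at/above the 5 mm gate; lengths
  inside (0, 5 mm) are below the tracker's detection limit and read 0 by
  design, so no error bound can apply there.
- Bubble pipeline: 5 replicates × 2000 bubbles, Lognormal(ln 150, 0.4²)
  µm at 10 µm/px in 1024² frames; microfoam check with
  Lognormal(ln 100, 0.3²) truncated at 500 µm.

## Known limitations

- Single straight tube per scene; no perspective or lens correction; no
  bubble-level tracking inside the plug.
- Linear phase model only: no exponential or biexponential degradation,
  no foam-half-time computation.
- Bubble volumes assume spheres; strongly non-circular objects are
  rejected rather than modelled.
- AVI input requires an imageio-compatible decoder at run time; numbered
  PNG/TIFF stacks are the portable path.
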