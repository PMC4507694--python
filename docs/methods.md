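# Methods

## Assay abstraction

A sample spot on an indoxylacetate strip darkens as the enzyme releases
indoxyl, which air-oxidizes to indigo. The pipeline treats the 8-bit
RGB photograph as the primary record and reduces each spot to the
per-channel intensity drop ΔI_c = I_c(0) − I_c(t_end). The sign
convention makes enzymatic darkening positive. Scores are computed per
replicate and then summarized: per-replicate scoring and score-level
averaging commute for the mean but not for the SD, and the replicate SD
of ΔI is what error bars on a calibration should carry. Whether
published error bars of this assay family are replicate-ΔI SDs or
propagated reading errors is generally not stated; we assume the
former.

## Sampling locus

Manual workflows read the color by clicking once at half the spot's
semi-diameter. One pixel is fragile against sensor noise, so the
default locus is the average over the 8 pixels nearest to equally
spaced positions on the circle of radius `radius/2` (angle 0 along +x),
rounded half-up back onto the 0–255 tone scale; `mode="point"` keeps
the strict single-pixel read (the 1-point ring and the point read are
identical by construction). Coordinates: origin top-left, x rightward,
y downward, integer pixel centers. JPEG input is accepted as-is; no
attempt is made to undo compression, white-balance, or convert color
spaces, since the intended capture setup is a fixed LED flash in a dark
tube. Automatic spot detection (median-offset threshold in the
highest-contrast channel, connected components, equivalent-area
circles) is a batch convenience only — quantitative runs take explicit
ROIs so numbers never depend on detection heuristics.

## Endpoint selection

The development curve flattens after about half an hour; longer waits
risk desiccation. `select_endpoint` operationalizes "the change is
minimal after this interval" as the earliest grid time t with mean
remaining change |I(t) − I(t_max)| ≤ f·|I(0) − I(t_max)|. With the
default f = 0.05 the single-exponential kinetics below put the endpoint
at 30 min (remaining change 4.5% at 30 min vs 7.7% at 25 min); f is a
parameter, and e.g. f = 0.10 accepts 25 min on the same curve. A flat
series returns t_max with a warning rather than an error.

## Calibration and LOD

The calibration curve is the four-parameter Boltzmann sigmoid on
linear activity (a log-activity variant is available behind a flag;
for two-fold dilution designs both parameterizations fit well, and
linear is the conventional choice for this curve family).
Initialization a1 = min y, a2 = max y, x0 = median x, dx = range(x)/4;
Levenberg–Marquardt with xtol 1e-8 and at most 10 000 evaluations;
points are unweighted (no replicate-variance weights by default).
Fits with dx < 0 are re-expressed with swapped asymptotes, which is the
same curve. R² = 1 − SS_res/SS_tot. Flat scores raise a fit error
(a2 − a1 unidentifiable); the requirement of ≥ 5 distinct levels
including a blank anchors both asymptote regions.

The S/N = 3 limit of detection inverts the curve at
blank_mean + 3·blank_sd, blanks being buffer-only ΔI replicates. When
that target does not exceed the fitted a1 (so inversion is undefined)
the low-end local slope s of the curve at activity 0 is used instead,
LOD = 3·blank_sd/s; the estimate records which route was taken. In the
regime where the curve is locally linear at the origin the two routes
agree to within a few percent, which the tests assert. Zero blank
scatter returns LOD = 0 flagged degenerate; a target above a2 raises
an error, since such an assay cannot detect at all. Channels are
ranked by ascending LOD, ties broken by descending dynamic range
(a2 − a1), then the fixed order R, G, B.

## Reference (Ellman) calculation

With two A412 readings dt seconds apart,

    activity = (ΔA/dt) / (ε·l) · (V_total/1000) / V_sample   [kat/mL],

i.e. the Beer–Lambert rate in mol·L⁻¹·s⁻¹ converted to moles of
product in the cuvette per second and normalized per mL of sample.
Defaults: ε = 14 150 L·mol⁻¹·cm⁻¹ (5-thio-2-nitrobenzoate, pH 7.4),
l = 1 cm, V_total = 1.0 mL (400 DTNB + 100 sample + 400 buffer + 100
substrate µL), V_sample = 0.1 mL, dt = 120 s. 1:1 stoichiometry
between thiocholine released and chromophore formed is assumed, the
standard reading of Ellman chemistry. The formula is validated by
dimensional-analysis tests and a hand-computed oracle
(ΔA = 0.1698 → 1.0 × 10⁻⁹ kat/mL at defaults), not against any
particular plasma value, since published katal-per-mL plasma figures
in this assay family cannot be back-derived without the raw ΔA.
Serial-dilution arithmetic (activities[k] = stock/factor^k) and the
cuvette concentration helper (c·v_added/v_total) round-trip the
standard two-fold plasma design; method comparison is ordinary least
squares of candidate on reference with R².

## Synthetic strips

The simulator is the package's study-condition generator, not a test
fixture. Each channel follows a single-exponential approach to an
asymptote,

    I_c(t) = i0_c − (i0_c − iinf_c)(1 − e^(−k(a)t)),  k(a) = k_ref·a/a_ref,

with defaults i0 = (221, 195, 158), iinf = (32, 68, 84),
k_ref = 0.1015 min⁻¹ at a_ref = 2.73 × 10⁻⁵ kat/mL. The single
exponential passes through the observed red trajectory
221 → 41 → 32 at 0/30/60 min almost exactly, and the 60-min green and
blue values serve as their asymptotes (their residual change at 60 min
is within noise); no mechanistic rate law is claimed. Rate proportional
to activity is the simplest first-order coupling. Channel dynamic
ranges therefore order R (189) > G (127) > B (74).

Noise has two levels, both Gaussian, both defaulting to the scatter of
pentaplicate strip work (score SDs of roughly 5–8 tone units):

* **replicate noise** (sd 4): one draw per spot per capture, applied
  to all three channels together. It emulates capture-to-capture
  luminance variation — flash output, drop placement, paper patch —
  which moves the channels jointly. Modeling it per-channel
  independent would make three-way LOD comparisons at n = 5 dominated
  by blank-SD sampling noise rather than by the channels' dynamic
  ranges.
* **pixel noise** (sd 2): independent per pixel and channel (sensor
  noise, paper texture).

Values are clipped to [0, 255] and quantized half-up to 8 bits, so
rendered images are honest uint8. Rendering draws one image per
(time, replicate) with all activity levels as left-to-right disks; the
manifest records every spot's ROI, true activity and noise-free model
color per time, making it the oracle for extraction tests. Every
stochastic operation takes an explicit seed and uses its own
`numpy.random.Generator`; there is no global RNG state.

Not modeled, hence outside what passing tests demonstrate about real
photographs: desiccation and spot spreading, illumination gradients,
JPEG artifacts, wettability differences between aqueous samples and
the ethanolic substrate coat, and any matrix or interferent chemistry
(interferents are represented only as a null effect on activity; an
`inhibition_fraction` scales effective activity for spiked-inhibitor
scenarios).

## Problem sizes and numerical choices

The default simulated study is 7 activity levels (two-fold stock
dilutions plus blank) × 5 replicates × 13 capture times, matching the
bench protocol. Statistical properties are asserted over 20 simulated
experiments (50 for Boltzmann parameter recovery), sizes at which the
medians and pass rates under test are stable; the whole suite runs in
seconds. Ring averages round half-up so readings stay on the integer
tone scale; score-summary SDs use the n−1 denominator (material at
n = 5). Degenerate inputs are handled explicitly rather than by
numeric accident: flat time courses warn, flat calibrations raise,
zero-noise blanks flag the LOD degenerate.

## Known limitations

The Boltzmann curve is a calibration convenience, not a mechanistic
dose–response: the simulator's score–activity relation is saturating
but inflection-free, and the sigmoid simply fits it well within the
calibrated range. Inverting scores near the saturation asymptote is
ill-conditioned, which is why out-of-range samples are flagged instead
of extrapolated. LOD values depend on blank noise that varies between
runs; orderings and recoveries are reproducible, absolute LODs are
not. The CLI's `extract` path currently consumes the simulator's
manifest for ROI geometry; photographs from other sources are handled
through the library API with explicit ROIs.
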