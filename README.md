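# stripquant

Quantification pipeline for colorimetric paper-strip enzyme assays read
with an ordinary smartphone camera, built around a butyrylcholinesterase
(BChE) activity assay on indoxylacetate-soaked filter paper.

**Who it is for.** Point-of-care and field diagnostics work where plasma
BChE activity is the readout — liver function screening, suspected
organophosphate or carbamate poisoning — and the only instrument is a
phone. The enzyme hydrolyses indoxylacetate to indoxyl, which oxidizes
to indigo, so an applied sample darkens the strip; a timed series of
8-bit RGB photographs captures that development.

**The model.** For a spot photographed at t = 0 and at an endpoint
t_end (30 min by default), the score of channel c ∈ {R, G, B} is the
intensity drop

    ΔI_c = I_c(0) − I_c(t_end)                (0–255 tone units)

computed per replicate (pentaplicate by default). The score is linked
to enzyme activity x (kat/mL of sample) by the Boltzmann sigmoid

    ΔI(x) = a2 + (a1 − a2) / (1 + exp((x − x0)/dx)),

fitted by unweighted least squares, with the closed-form inverse
x(ΔI) = x0 + dx·ln((ΔI − a1)/(a2 − ΔI)) used for quantification. The
limit of detection follows the S/N = 3 convention: the activity whose
predicted score exceeds the blank mean by three blank standard
deviations. A re-implemented Ellman spectrophotometric calculation
(ΔA412 over dt, ε = 14 150 L·mol⁻¹·cm⁻¹, 1 cm path) provides reference
activities, and ordinary least squares compares the two methods.

Because no image corpus ships with the package, a kinetics-driven
simulator renders ground-truthed synthetic strips: each channel decays
from its paper baseline toward an indigo endpoint with first-order rate
proportional to activity (defaults reproduce R 221 → 41 → 32 at
0/30/60 min at the reference activity 2.73 × 10⁻⁵ kat/mL), with
replicate- and pixel-level noise and 8-bit quantization.

## Worked example

Simulate a pentaplicate two-fold dilution series (stock
2.73 × 10⁻⁵ kat/mL, five dilutions plus a buffer blank), score it at
30 min, calibrate the red channel and quantify:

```sh
stripquant simulate  --outdir demo --seed 42
stripquant score     --readings demo/readings.csv --t-end 30 --out demo/scores.csv
stripquant calibrate --scores demo/scores.csv --activities demo/activities.csv \
                     --channel R --out demo/cal.json
stripquant quantify  --scores demo/scores.csv --calibration demo/cal.json \
                     --out demo/est.csv
```

(`demo/activities.csv` maps spot labels to known activities; the
simulator's `manifest.json` carries the ground truth.) The calibrate
step prints

```
R: R^2=0.9912, LOD=1.67e-06 kat/mL (invert)
```

— the Boltzmann fit explains 99.1% of the score variance and the
S/N = 3 detection limit sits well below the stock activity. The
quantified table starts

```
label,score,activity,flag
lvl00,177.4,2.7799017570814367e-05,ok
lvl01,148.2,1.3476585274144885e-05,ok
lvl02,99.6,6.842116795666147e-06,ok
```

so the undiluted stock (true activity 2.73 × 10⁻⁵) is recovered at
2.78 × 10⁻⁵ kat/mL, within 2%, and the two-fold structure of the series
is preserved. Samples whose scores fall below the detection limit are
flagged `below LOD` rather than silently reported.

The same operations are available as a library (`stripquant.render_series`,
`delta_frame`, `fit_boltzmann`, `invert`, `lod_sn3`,
`activity_from_absorbance`, …); see `docs/methods.md` for the model
details and design choices.

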