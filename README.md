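# fuzzydose

A two-stage Mamdani fuzzy expert system for remote diabetes screening and
insulin-dose recommendation, with a deterministic clinical bolus calculator
and a synthetic vitals-stream generator that stands in for the wearable
sensing hardware.

**This is a research prototype of a decision-support pipeline. It makes no
claim of clinical validity and must not be used to dose insulin.**

## What it computes

**Stage 1 — screening.** Blood sugar *x* (mmol/L) and heart rate (BPM) are
fuzzified through trapezoidal membership functions (blood sugar: Low ≤3.9,
Normal 4.0–5.4, Prediabetic 5.5–6.9, Diabetic >7.0; heart rate: Bradycardia
<58, Normal 60–100, Tachycardia >102). A 12-rule base — only Normal × Normal
is Healthy — fires with AND = min, and the health-state score on [0, 100] is
defuzzified either by a strength-weighted average of one representative
value per label (Unhealthy 40, Healthy 60),

    score = Σᵢ sᵢ·rep(cᵢ) / Σᵢ sᵢ ,

or by the full Mamdani clip/max-aggregate/centroid method on a uniform
grid. Scores ≤40 are labeled unhealthy, ≥60 healthy, and anything between
borderline.

**Stage 2 — dosing.** For a patient with Unhealthy membership and glucose in
the diabetic range, a four-input system (health state × diabetic level ×
weight × carbohydrate intake, 27 rules, every rule gated on Unhealthy) maps
to an insulin dose on [0, 44] units with labels Low / Medium / High / Very
High.

**Clinical formula.** The standard bolus arithmetic the rule table
abstracts:

    TDI = 0.55 · weight (kg)          CCR = 500 / TDI
    CHO dose = carbs (g) / CCR
    correction = max(0, (BG·18 − 120) · TDI / 1800)   [BG in mmol/L]
    total = CHO dose + correction

**Telemetry.** Truncated-normal vitals streams per patient archetype
(healthy, prediabetic, diabetic, bradycardic, tachycardic), sampled every
8 h, written/read as CSV or JSON-lines.

## Worked example

```sh
$ fuzzydose diagnose --blood-sugar 5.42 --heart-rate 58.7
health-state score: 45
label: borderline
```

At 5.42 mmol/L the blood sugar is 0.8 Normal / 0.2 Prediabetic; at 58.7 BPM
the heart rate is 0.65 Bradycardia / 0.35 Normal. Four rules fire (0.65 and
two × 0.2 toward Unhealthy, 0.35 toward Healthy) and the weighted average of
the representatives 40/60 gives 45 — the patient is borderline, not yet
fully unhealthy.

```sh
$ fuzzydose dose --health-score 26.5 --glucose 8.65 --weight 71.6 \
      --carbs 260 --method centroid --with-formula
insulin dose: 25.00 units (Medium)
clinical formula:
  TDI: 39.38 units/day
  CCR: 12.70 g/unit
  CHO dose: 20.48 units
  correction dose: 0.78 units
  total: 21.26 units
```

Here only one rule fires (Medium diabetic level, Moderate weight, Medium
carbohydrate → Medium dose) at full strength, and the centroid of the
symmetric Medium trapezoid (20/22/28/30) is exactly 25 units. The formula
section shows the deterministic breakdown for the same inputs: a 71.6 kg
patient needs TDI = 39.38 units/day, the 260 g carbohydrate intake costs
20.48 units, and the 8.65 mmol/L glucose adds a 0.78-unit correction.

End-to-end, from simulated sensors:

```sh
fuzzydose simulate --archetype diabetic --n 90 --seed 42 --out readings.csv
fuzzydose pipeline --readings readings.csv --profile profile.json --out results.csv
```

Every subcommand takes `--format json` for machine-readable output,
`--explain` attaches the fired-rule trace, and `--dump-config` prints the
packaged system definitions (editable YAML).

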