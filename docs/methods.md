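# Methods

## Inference model

Both clinical systems are single-output Mamdani systems over piecewise-linear
membership functions. A term is a trapezoid (a, b, c, d): linear rise a→b,
plateau [b, c] at grade 1, linear fall c→d. Boundary terms are *open
shoulders*: with `open_left` the grade is 1 for every x ≤ b, with
`open_right` for every x ≥ c. Grades are exact at breakpoints (1 on the
closed plateau, 0 at closed feet).

Rule antecedents are pure conjunctions evaluated with AND = min; no OR or
NOT connectives exist in either rule base, so none are implemented. Rules
whose strength is exactly 0 are dropped from the trace; they cannot affect
either defuzzifier, which are aggregate-based, so no tie-breaking is needed.

Two defuzzifiers are provided because the source material is ambiguous: the
narrative names the centroid method, but every hand calculation is a
strength-weighted average of a single representative value per output label.
Both are first-class and selectable (`weighted` is the default, because it
is the variant whose printed results are reproducible):

- **weighted_representative** — Σ sᵢ·rep(cᵢ) / Σ sᵢ. Representatives ship
  with each system: 40/60 for the health state; 20/25/33/40 for insulin.
  The insulin representatives are the plateau midpoints (Low uses its
  plateau edge 20) — the hand calculations use 22 and 28 inconsistently for
  Medium, and midpoints are the only self-consistent choice. They are
  configurable per run.
- **mamdani_centroid** — each consequent trapezoid is clipped at its
  aggregated strength (max over rules sharing the consequent), clipped terms
  are combined pointwise by max on a uniform grid over the output universe,
  and the centroid ∫x·μ dx / ∫μ dx is returned. Integrals use trapezoid
  weights on the grid (default step 0.01 output units); with the default
  step this agrees with the closed-form centroid of any single clipped
  trapezoid to well under 10⁻³. Open shoulders are truncated at the output
  universe bounds ([0, 100] for the health state, [0, 44] insulin units),
  since the centroid of an unbounded shoulder is undefined.

## System definitions

The two systems ship as YAML under `fuzzydose/data/` and are the single
source of truth; `--dump-config` prints them and user files in the same
format can replace them.

Universes are not stated by the source partitions and were fixed once to
cover all term supports: blood sugar [0, 12] mmol/L, heart rate [30, 180]
BPM, health state [0, 100], diabetic level [7, 12] mmol/L, weight [50, 100]
kg, carbohydrate [150, 360] g, insulin [0, 44] units. Inputs outside a
universe by at most a configurable clamp tolerance (default 0) are clamped
to the bound; beyond that, a domain error names the variable and bounds —
the weight High term vanishes above 100 kg, leaving no defined behavior to
extrapolate.

Two printed equations in the source partitions are internally inconsistent
and were reconstructed from the stated ranges: the Medium diabetic-level
term (printed as a duplicate of Low) becomes rise 8.0→8.4, plateau 8.4→8.8,
fall 8.8→9.1, meeting the High rise; and inequality directions on two
shoulder terms (Bradycardia, weight Low) follow the stated ranges (<58 BPM,
50–65 kg) rather than the printed relational signs. On every crossover of
adjacent terms the configured grades sum to exactly 1 (partition of unity),
which the property tests assert for all nine variables.

All 27 dose rules carry an explicit `health_state == Unhealthy` conjunct:
the rule table enumerates only diabetic level × weight × carbohydrate, but
the worked inference conjoins Unhealthy in every rule and no rule prescribes
insulin to a Healthy patient. Dosing therefore raises "not applicable" for
a health score ≥ 60 (zero Unhealthy membership). The dose label reported
beside the crisp dose is the consequent with maximal aggregated strength,
ties broken toward the lower dose.

Score labels: unhealthy ≤ 40, healthy ≥ 60, borderline strictly between —
the three-way reading of a score like 45, which the screening narrative
treats as neither state. The boundary scores themselves attach to the
adjacent plateau (40 → unhealthy, 60 → healthy).

## Clinical formula

TDI = 0.55·weight, CCR = 500/TDI, CHO dose = carbs/CCR, correction =
(BG·18 − 120)·TDI/1800 with BG converted from mmol/L at 18.0 mg/dL per
mmol/L. The correction is floored at zero below the 120 mg/dL baseline:
negative insulin corrections are meaningless for a bolus calculator, and
the source never considers that branch. All constants live in
`ClinicalConstants` and are overridable. The identity CCR·TDI = 500 holds
to one ulp (an IEEE divide-then-multiply round trip is not bit-exact).

## Synthetic telemetry

The generator emulates the wearable subsystem: per-archetype truncated
normal draws for blood sugar and heart rate, sampled every 8 hours.
Defaults center on the stage-1 term plateaus — healthy BS N(4.7, 0.3)
mmol/L with HR N(80, 8) BPM; prediabetic BS N(6.2, 0.3); diabetic
BS N(8.6, 0.5) truncated below at 7.05 mmol/L so every reading is in the
diabetic range and stage-2 dosing always applies; bradycardic HR N(50, 4);
tachycardic HR N(112, 5). Truncation at the universe bounds avoids clamp
errors. Streams round-trip exactly through CSV and JSON-lines (floats
written at full repr precision, ISO-8601 timestamps).

What the generator does *not* emulate: sensor bias and drift, dropout,
irregular sampling, intra-day glucose dynamics (meals, insulin action), or
any correlation between glucose and heart rate. Tests passing on these
streams show the inference pipeline is correct on in-universe, well-formed
readings; they say nothing about robustness to real sensor artifacts.

## Numerical choices and test oracles

- Centroid grid: step 0.01 output units, trapezoid-weighted sums; refining
  the step by 10× moves tested centroids by far less than 10× the step.
- Independent oracles in the tests (never in the package): a closed-form
  centroid of a universe-truncated trapezoid, and brute-force numerical
  integration at step 10⁻⁴.
- Property tests are seeded (`numpy` generators with fixed seeds;
  hypothesis derandomized): partition of unity to 10⁻⁹, rule-strength
  monotonicity, weighted-defuzzifier invariance under splitting a fired
  rule's strength, dose-table severity monotone in each antecedent
  (exhaustive over the 27 rules), crisp-dose monotonicity on single-input
  sweeps, and full input-space rule coverage (10⁴ random stage-1 pairs).
- Problem sizes: statistical telemetry checks use 1000 readings at a fixed
  seed; coverage sweeps use 500–10⁴ random points. The whole suite runs in
  a few seconds.

## Known limitations

- Only trapezoid/shoulder membership shapes; no Gaussian/sigmoid terms, no
  Sugeno/TSK inference, no rule learning.
- The dose scale tops out at 44 units and the rule base is only defined for
  the configured universes; no basal/bolus split, insulin-on-board, age or
  activity inputs.
- Two printed downstream numbers in the source material (a final worked
  dose and a correction-dose/total pair) do not follow from the stated
  formulas and memberships; the implementation reproduces the stated
  formulas, and its outputs for those inputs (≈21.47 units; 0.78 units
  correction) are the values the tests assert.
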