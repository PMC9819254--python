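# Stage-2 system: health state x diabetic level x weight x carbohydrate
# intake -> insulin dose.  The 27 dose rules enumerate diabetic level x
# weight x carbohydrate; every rule is additionally gated on the stage-1
# health state being Unhealthy (no rule prescribes insulin to a Healthy
# patient).  Representatives for the weighted method are the plateau
# midpoints of the insulin terms (Low uses its plateau edge 20).
name: insulin-dosing
inputs:
  - name: health_state
    units: score
    universe: [0.0, 100.0]
    terms:
      - {label: Unhealthy, points: [40.0, 40.0, 40.0, 60.0], open_left: true}
      - {label: Healthy, points: [40.0, 60.0, 60.0, 60.0], open_right: true}
  - name: diabetic_level
    units: mmol/L
    universe: [7.0, 12.0]
    terms:
      - {label: Low, points: [7.0, 7.4, 8.0, 8.4]}
      - {label: Medium, points: [8.0, 8.4, 8.8, 9.1]}
      - {label: High, points: [8.8, 9.1, 9.1, 9.1], open_right: true}
  - name: weight
    units: kg
    universe: [50.0, 100.0]
    terms:
      - {label: Low, points: [65.0, 65.0, 65.0, 70.0], open_left: true}
      - {label: Moderate, points: [65.0, 70.0, 75.0, 80.0]}
      - {label: High, points: [75.0, 80.0, 95.0, 100.0]}
  - name: carbohydrate
    units: g
    universe: [150.0, 360.0]
    terms:
      - {label: Low, points: [235.0, 235.0, 235.0, 240.0], open_left: true}
      - {label: Medium, points: [235.0, 240.0, 275.0, 280.0]}
      - {label: High, points: [275.0, 280.0, 355.0, 360.0]}
output:
  name: insulin_dose
  units: units
  universe: [0.0, 44.0]
  terms:
    - {label: Low, points: [20.0, 20.0, 20.0, 22.0], open_left: true}
    - {label: Medium, points: [20.0, 22.0, 28.0, 30.0]}
    - {label: High, points: [28.0, 30.0, 36.0, 38.0]}
    - {label: Very High, points: [36.0, 38.0, 42.0, 44.0]}
rules:
  - {id: 1, if: {health_state: Unhealthy, diabetic_level: Low, weight: Low, carbohydrate: Low}, then: Low}
  - {id: 2, if: {health_state: Unhealthy, diabetic_level: Low, weight: Low, carbohydrate: Medium}, then: Low}
  - {id: 3, if: {health_state: Unhealthy, diabetic_level: Low, weight: Low, carbohydrate: High}, then: Medium}
  - {id: 4, if: {health_state: Unhealthy, diabetic_level: Low, weight: Moderate, carbohydrate: Low}, then: Low}
  - {id: 5, if: {health_state: Unhealthy, diabetic_level: Low, weight: Moderate, carbohydrate: Medium}, then: Medium}
  - {id: 6, if: {health_state: Unhealthy, diabetic_level: Low, weight: Moderate, carbohydrate: High}, then: Medium}
  - {id: 7, if: {health_state: Unhealthy, diabetic_level: Low, weight: High, carbohydrate: Low}, then: Medium}
  - {id: 8, if: {health_state: Unhealthy, diabetic_level: Low, weight: High, carbohydrate: Medium}, then: Medium}
  - {id: 9, if: {health_state: Unhealthy, diabetic_level: Low, weight: High, carbohydrate: High}, then: High}
  - {id: 10, if: {health_state: Unhealthy, diabetic_level: Medium, weight: Low, carbohydrate: Low}, then: Low}
  - {id: 11, if: {health_state: Unhealthy, diabetic_level: Medium, weight: Low, carbohydrate: Medium}, then: Low}
  - {id: 12, if: {health_state: Unhealthy, diabetic_level: Medium, weight: Low, carbohydrate: High}, then: Medium}
  - {id: 13, if: {health_state: Unhealthy, diabetic_level: Medium, weight: Moderate, carbohydrate: Low}, then: Low}
  - {id: 14, if: {health_state: Unhealthy, diabetic_level: Medium, weight: Moderate, carbohydrate: Medium}, then: Medium}
  - {id: 15, if: {health_state: Unhealthy, diabetic_level: Medium, weight: Moderate, carbohydrate: High}, then: Medium}
  - {id: 16, if: {health_state: Unhealthy, diabetic_level: Medium, weight: High, carbohydrate: Low}, then: Medium}
  - {id: 17, if: {health_state: Unhealthy, diabetic_level: Medium, weight: High, carbohydrate: Medium}, then: Medium}
  - {id: 18, if: {health_state: Unhealthy, diabetic_level: Medium, weight: High, carbohydrate: High}, then: High}
  - {id: 19, if: {health_state: Unhealthy, diabetic_level: High, weight: Low, carbohydrate: Low}, then: Low}
  - {id: 20, if: {health_state: Unhealthy, diabetic_level: High, weight: Low, carbohydrate: Medium}, then: Medium}
  - {id: 21, if: {health_state: Unhealthy, diabetic_level: High, weight: Low, carbohydrate: High}, then: Medium}
  - {id: 22, if: {health_state: Unhealthy, diabetic_level: High, weight: Moderate, carbohydrate: Low}, then: Medium}
  - {id: 23, if: {health_state: Unhealthy, diabetic_level: High, weight: Moderate, carbohydrate: Medium}, then: Medium}
  - {id: 24, if: {health_state: Unhealthy, diabetic_level: High, weight: Moderate, carbohydrate: High}, then: High}
  - {id: 25, if: {health_state: Unhealthy, diabetic_level: High, weight: High, carbohydrate: Low}, then: Medium}
  - {id: 26, if: {health_state: Unhealthy, diabetic_level: High, weight: High, carbohydrate: Medium}, then: High}
  - {id: 27, if: {health_state: Unhealthy, diabetic_level: High, weight: High, carbohydrate: High}, then: Very High}
representatives:
  Low: 20.0
  Medium: 25.0
  High: 33.0
  Very High: 40.0
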