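# Stage-1 system: blood sugar x heart rate -> health state.
# Breakpoints follow the published clinical partitions: blood sugar
# Low <=3.9, Normal 4.0-5.4, Prediabetic 5.5-6.9, Diabetic >7.0 mmol/L;
# heart rate Bradycardia <58, Normal 60-100, Tachycardia >102 BPM.
# Only Normal x Normal is Healthy; the other 11 combinations are Unhealthy.
name: diabetes-diagnosis
inputs:
  - name: blood_sugar
    units: mmol/L
    universe: [0.0, 12.0]
    terms:
      - {label: Low, points: [3.9, 3.9, 3.9, 4.0], open_left: true}
      - {label: Normal, points: [3.9, 4.0, 5.4, 5.5]}
      - {label: Prediabetic, points: [5.4, 5.5, 6.9, 7.0]}
      - {label: Diabetic, points: [6.9, 7.0, 7.0, 7.0], open_right: true}
  - name: heart_rate
    units: BPM
    universe: [30.0, 180.0]
    terms:
      - {label: Bradycardia, points: [58.0, 58.0, 58.0, 60.0], open_left: true}
      - {label: Normal, points: [58.0, 60.0, 100.0, 102.0]}
      - {label: Tachycardia, points: [100.0, 102.0, 102.0, 102.0], open_right: true}
output:
  name: health_state
  units: score
  universe: [0.0, 100.0]
  terms:
    - {label: Unhealthy, points: [40.0, 40.0, 40.0, 60.0], open_left: true}
    - {label: Healthy, points: [40.0, 60.0, 60.0, 60.0], open_right: true}
rules:
  - {id: 1, if: {blood_sugar: Low, heart_rate: Bradycardia}, then: Unhealthy}
  - {id: 2, if: {blood_sugar: Low, heart_rate: Normal}, then: Unhealthy}
  - {id: 3, if: {blood_sugar: Low, heart_rate: Tachycardia}, then: Unhealthy}
  - {id: 4, if: {blood_sugar: Normal, heart_rate: Bradycardia}, then: Unhealthy}
  - {id: 5, if: {blood_sugar: Normal, heart_rate: Normal}, then: Healthy}
  - {id: 6, if: {blood_sugar: Normal, heart_rate: Tachycardia}, then: Unhealthy}
  - {id: 7, if: {blood_sugar: Prediabetic, heart_rate: Bradycardia}, then: Unhealthy}
  - {id: 8, if: {blood_sugar: Prediabetic, heart_rate: Normal}, then: Unhealthy}
  - {id: 9, if: {blood_sugar: Prediabetic, heart_rate: Tachycardia}, then: Unhealthy}
  - {id: 10, if: {blood_sugar: Diabetic, heart_rate: Bradycardia}, then: Unhealthy}
  - {id: 11, if: {blood_sugar: Diabetic, heart_rate: Normal}, then: Unhealthy}
  - {id: 12, if: {blood_sugar: Diabetic, heart_rate: Tachycardia}, then: Unhealthy}
representatives:
  Unhealthy: 40.0
  Healthy: 60.0
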