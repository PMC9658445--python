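# Worked-example configuration: the three Araripe UGG geosite trails.
# All values are transcriptions of the published field tables; route
# tables are the CSV files alongside this config. Two printed values are
# repaired to restore internal consistency: the end altitude of Sítio
# Fundão Route 1 is printed as 462 m (rounded); 462.3 m restores the
# trail's accumulated positive gradient of 52.3 m. And the Sítio Fundão
# climate grid as printed sums to 48 against its own printed per-cycle
# subtotals (15, 15, 9, 10; total 49); the humidity cell of cycle II is
# raised from 2 to 3 to match the printed subtotals.
references:
  aquatic: 15
  climate: 72
  wellness: 60
  geodiversity: 1600
  shannon_h: 5.5
  severity: 26
  orientation: 5
  surface: 6
network:
  gamma: 0.5
  n_lambda: 100
  lambda_min_ratio: 0.01
trails:
  - name: "Sítio Fundão"
    route_table: sitio_fundao.csv
    orientation: 2
    surface: 3
    severity_checked: [g, h, i, j, k, l, n, o, s, t, u]
    aquatic: {availability: 3, interaction: 2, bathing: 2, potability: 2, risk: 2}
    climate:
      insolation: [3, 2, 1, 1]
      temperature: [2, 3, 1, 1]
      rainfall: [3, 2, 1, 2]
      humidity: [3, 3, 1, 2]
      winds: [1, 2, 3, 2]
      green_tunnel: [3, 3, 2, 2]
    wellness: {visions: 9, sounds: 8, odors: 4, interaction: 12}
    geodiversity: {scientific: 280, degradation_risk: 200, educational: 335, touristic: 300}
    shannon_h: 4.65
    equivalent_km: 2.320
    att: "17 min 45 s"
    att_pct: 29.9
  - name: "Missão Velha Waterfall"
    route_table: missao_velha.csv
    orientation: 1
    surface: 2
    severity_checked: [c, h, i, m, s, t, u]
    aquatic: {availability: 3, interaction: 1, bathing: 1, potability: 2, risk: 1}
    climate:
      insolation: [3, 2, 1, 1]
      temperature: [2, 3, 1, 1]
      rainfall: [3, 2, 1, 2]
      humidity: [3, 2, 1, 2]
      winds: [1, 2, 3, 2]
      green_tunnel: [3, 2, 1, 2]
    wellness: {visions: 11, sounds: 9, odors: 5, interaction: 11}
    geodiversity: {scientific: 190, degradation_risk: 295, educational: 335, touristic: 270}
    shannon_h: 3.6
    equivalent_km: 5.1
    att: "21 min 34 s"
    att_pct: 22.4
  - name: "Pontal de Santa Cruz"
    route_table: pontal_santa_cruz.csv
    orientation: 1
    surface: 4
    severity_checked: [a, b, c, e, h, i, j, n, s, t, u]
    aquatic: {availability: 2, interaction: 0, bathing: 0, potability: 3, risk: 0}
    climate:
      insolation: [3, 2, 1, 1]
      temperature: [2, 3, 1, 1]
      rainfall: [3, 2, 1, 2]
      humidity: [3, 2, 1, 2]
      winds: [1, 2, 3, 2]
      green_tunnel: [3, 2, 1, 2]
    wellness: {visions: 7, sounds: 6, odors: 4, interaction: 10}
    geodiversity: {scientific: 190, degradation_risk: 225, educational: 340, touristic: 320}
    shannon_h: 2.9
    equivalent_km: 1.527
    att: "28 min 30 s"
    att_pct: 139.4
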