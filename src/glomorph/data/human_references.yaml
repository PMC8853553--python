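# Clinical reference values for hypertensive glomerulopathy (12 studies).
# Percentages are the averaged published figures; ranges are kept as
# ranges, not collapsed.  score_* fields carry the studies that reported
# a glomerular-area score instead of (or besides) lesion percentages.
- study_label: Fogo
  condition: essential hypertension
  n_patients: 46
  fsgs_pct: 5.0
  ggs_pct: 43.0
  ggs_pct_sd: 26.0
- study_label: Caetano
  condition: essential hypertension
  n_patients: 81
  ggs_pct: 20.0
  ggs_pct_sd: 3.0
- study_label: Ballardie
  condition: IgA nephropathy with hypertension
  n_patients: 36
  score_mean: 1.6
  score_max: 3.0
- study_label: Hughson
  condition: hypertensive nephropathy
  n_patients: 239
  ggs_pct: 29.0
  score_mean: 1.4
  score_max: 4.0
- study_label: Marcantoni
  condition: hypertensive nephrosclerosis
  n_patients: 62
  ggs_pct: 42.0
  ggs_pct_sd: 3.0
- study_label: Hill
  condition: essential hypertension
  n_patients: 30
  fsgs_pct: 24.0
  ggs_pct: 18.0
- study_label: Ikee
  condition: IgA nephropathy with hypertension
  n_patients: 38
  ggs_pct: 25.0
- study_label: Imakiire
  condition: essential hypertension
  n_patients: 31
  ggs_pct: 21.0
  ggs_pct_sd: 15.0
- study_label: Bige
  condition: chronic kidney disease
  n_patients: 58
  ggs_pct: 13.0
  ggs_pct_range: [0.0, 96.0]
- study_label: Liang
  condition: benign and malignant essential hypertension
  n_patients: 194
  fsgs_pct: 5.5
  fsgs_pct_range: [5.0, 6.0]
  ggs_pct: 34.0
  ggs_pct_range: [18.0, 50.0]
- study_label: Denic
  condition: normal aging
  n_patients: 1638
  ggs_pct: 27.0
- study_label: Lee
  condition: IgA nephropathy with hypertension
  n_patients: 340
  fsgs_pct: 6.0
  ggs_pct: 21.0
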