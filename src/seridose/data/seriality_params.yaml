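# Relative seriality dose-response parameter sets for late (12-month)
# patient-reported symptoms after prostate(-bed) IMRT, with 95% ranges.
# Bladder: frequency of urinating at night (u2); parallel-like (tiny s).
# Rectum: diarrhea / loose watery stools (r1); serial-like (s = 1).
organs:
  bladder:
    d50_gy: 80.9
    d50_ci: [65.7, 108.2]
    gamma: 0.44
    gamma_ci: [0.31, 0.57]
    s: 0.0001
    s_ci: [0.00001, 0.0007]
    symptom: u2
  rectum:
    d50_gy: 67.0
    d50_ci: [64.5, 72.0]
    gamma: 2.5
    gamma_ci: [0.8, 7.1]
    s: 1.0
    s_ci: [0.7, 7.0]
    symptom: r1
symptom_organ_map:
  u2: bladder
  r1: rectum
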